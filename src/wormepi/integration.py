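"""Candidate-gene integration funnel.

Differential histone-mark windows are mapped onto genes (gene body plus
an upstream promoter interval), genes carrying both the H3K79me2 and
H3K79me3 enrichment are intersected with transcriptionally upregulated
genes from an RNA-seq differential-expression table, and the surviving
candidates' promoters are extracted and scanned for a transcription-
factor binding motif (e.g. SKN-1) with a log-odds position weight
matrix on both strands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from intervaltree import IntervalTree

from .chipseq import GenomeAnnotation

__all__ = [
    "GeneMarkCalls",
    "CandidateFilter",
    "PromoterSet",
    "Pwm",
    "MotifScanResult",
    "map_sites_to_genes",
    "intersect_mark_sets",
    "filter_upregulated",
    "select_candidates",
    "extract_promoters",
    "scan_motif",
    "read_fasta",
    "write_fasta",
]


@dataclass
class GeneMarkCalls:
    """Per-gene differential flags for one mark, with supporting windows."""

    mark: str
    up: dict[str, list[int]] = field(default_factory=dict)  # gene -> window idx
    down: dict[str, list[int]] = field(default_factory=dict)
    n_unassigned: int = 0

    @property
    def up_genes(self) -> set[str]:
        return set(self.up)

    @property
    def down_genes(self) -> set[str]:
        return set(self.down)


def map_sites_to_genes(
    sites: pd.DataFrame,
    ann: GenomeAnnotation,
    promoter_upstream: int = 1000,
    mark: str = "",
    nearest_tss_only: bool = False,
) -> GeneMarkCalls:
    """Assign significant differential windows to overlapping genes.

    A window is assigned to every gene whose body or upstream promoter
    interval (``promoter_upstream`` bp 5' of the TSS, strand-aware) it
    overlaps by >= 1 bp; with ``nearest_tss_only`` a multi-gene window
    goes only to the gene with the closest TSS. Unassigned windows are
    counted, not dropped silently.
    """
    sig = sites[sites["significant"]] if "significant" in sites.columns else sites
    trees: dict[str, IntervalTree] = {}
    tss = ann.tss()
    for _, g in ann.genes.iterrows():
        if g["strand"] == "+":
            lo = max(0, g["start"] - promoter_upstream)
            hi = g["end"]
        else:
            lo = g["start"]
            hi = g["end"] + promoter_upstream
        trees.setdefault(g["chrom"], IntervalTree()).addi(lo, hi, g["gene_id"])
    calls = GeneMarkCalls(mark=mark)
    for idx, row in sig.iterrows():
        tree = trees.get(row["chrom"])
        hits = tree.overlap(row["start"], row["end"]) if tree else set()
        if not hits:
            calls.n_unassigned += 1
            continue
        genes = [h.data for h in hits]
        if nearest_tss_only and len(genes) > 1:
            mid = (row["start"] + row["end"]) / 2.0
            genes = [min(genes, key=lambda g: abs(tss[g] - mid))]
        direction = row.get("direction", "higher_in_treated")
        bucket = calls.up if direction == "higher_in_treated" else calls.down
        for g in genes:
            bucket.setdefault(g, []).append(int(idx))
    return calls


def intersect_mark_sets(
    calls_me2: GeneMarkCalls, calls_me3: GeneMarkCalls
) -> tuple[set[str], dict[str, int]]:
    """Genes enriched for both marks, plus all Venn region counts."""
    a, b = calls_me2.up_genes, calls_me3.up_genes
    both = a & b
    venn = {
        "me2_only": len(a - b),
        "me3_only": len(b - a),
        "both": len(both),
        "union": len(a | b),
    }
    return both, venn


@dataclass(frozen=True)
class CandidateFilter:
    """Strict thresholds for calling a gene transcriptionally upregulated."""

    fc_min: float = 1.5
    p_max: float = 0.01
    q_max: float = 0.05

    def __post_init__(self) -> None:
        if self.fc_min <= 1:
            raise ValueError("fc_min must exceed 1")
        if not (0 < self.p_max <= 1 and 0 < self.q_max <= 1):
            raise ValueError("p_max and q_max must be in (0, 1]")


def filter_upregulated(de: pd.DataFrame, f: CandidateFilter = CandidateFilter()) -> set[str]:
    """Genes with fold change > fc_min AND p < p_max AND q < q_max (all strict).

    ``de`` columns: gene_id, fc (linear treated/control), p, q.
    """
    req = {"gene_id", "fc", "p", "q"}
    missing = req - set(de.columns)
    if missing:
        raise ValueError(f"DE table missing columns: {sorted(missing)}")
    if (de["fc"] <= 0).any():
        raise ValueError("fold changes must be positive")
    keep = (de["fc"] > f.fc_min) & (de["p"] < f.p_max) & (de["q"] < f.q_max)
    return set(de.loc[keep, "gene_id"])


def select_candidates(
    both_marks: set[str],
    upregulated: set[str],
    de: pd.DataFrame | None = None,
    calls_me2: GeneMarkCalls | None = None,
    calls_me3: GeneMarkCalls | None = None,
) -> pd.DataFrame:
    """Intersect both-mark genes with upregulated genes, carrying provenance."""
    cands = sorted(both_marks & upregulated)
    rows = []
    de_idx = de.set_index("gene_id") if de is not None else None
    for g in cands:
        row: dict = {"gene_id": g}
        if de_idx is not None and g in de_idx.index:
            row.update(
                fc=float(de_idx.at[g, "fc"]),
                p=float(de_idx.at[g, "p"]),
                q=float(de_idx.at[g, "q"]),
            )
        if calls_me2 is not None:
            row["me2_windows"] = ",".join(map(str, calls_me2.up.get(g, [])))
        if calls_me3 is not None:
            row["me3_windows"] = ",".join(map(str, calls_me3.up.get(g, [])))
        rows.append(row)
    return pd.DataFrame(rows, columns=rows[0].keys() if rows else ["gene_id"])


@dataclass
class PromoterSet:
    """Promoter sequences 5'->3' toward the gene, with genomic provenance."""

    records: pd.DataFrame  # gene_id, chrom, start, end, strand, span, sequence

    def sequences(self) -> dict[str, str]:
        return dict(zip(self.records["gene_id"], self.records["sequence"]))

    def __len__(self) -> int:
        return len(self.records)


def extract_promoters(
    ann: GenomeAnnotation,
    genome: dict[str, str],
    genes: set[str] | None = None,
    min_len: int = 1000,
    scan_len: int = 1000,
) -> PromoterSet:
    """Upstream intergenic promoters longer than ``min_len``.

    The promoter span runs from the TSS upstream to the nearest annotated
    neighbour boundary (any gene, either strand) or the chromosome edge.
    Genes with span > min_len are retained and the TSS-proximal
    ``scan_len`` bp returned, reverse-complemented for minus-strand genes
    so the sequence reads 5'->3' toward the gene.
    """
    tss = ann.tss()
    g = ann.genes
    wanted = g if genes is None else g[g["gene_id"].isin(genes)]
    rows = []
    for _, gene in wanted.iterrows():
        chrom = gene["chrom"]
        if chrom not in genome:
            raise KeyError(f"gene {gene['gene_id']} chromosome {chrom} not in genome")
        seq_len = len(genome[chrom])
        others = g[(g["chrom"] == chrom) & (g["gene_id"] != gene["gene_id"])]
        if gene["strand"] == "+":
            t = int(gene["start"])
            upstream_ends = others.loc[others["end"] <= t, "end"]
            bound = int(upstream_ends.max()) if len(upstream_ends) else 0
            span = t - bound
            if span <= min_len:
                continue
            s, e = t - min(scan_len, span), t
            seq = genome[chrom][s:e]
        else:
            t = int(gene["end"])
            downstream_starts = others.loc[others["start"] >= t, "start"]
            bound = int(downstream_starts.min()) if len(downstream_starts) else seq_len
            span = bound - t
            if span <= min_len:
                continue
            s, e = t, t + min(scan_len, span)
            seq = str(Seq(genome[chrom][s:e]).reverse_complement())
        rows.append(
            {
                "gene_id": gene["gene_id"],
                "chrom": chrom,
                "start": s,
                "end": e,
                "strand": gene["strand"],
                "span": span,
                "sequence": seq.upper(),
            }
        )
    return PromoterSet(
        pd.DataFrame(
            rows,
            columns=["gene_id", "chrom", "start", "end", "strand", "span", "sequence"],
        )
    )


_BASES = "ACGT"
_COMP = str.maketrans("ACGTN", "TGCAN")


@dataclass
class Pwm:
    """Position weight matrix with log2-odds scoring against a background.

    ``probs`` has shape (L, 4) in A,C,G,T order; rows sum to 1. Counts
    are accepted and normalized with a small pseudo-probability so zero
    cells stay finite.
    """

    probs: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("PWM must have shape (L, 4)")
        if np.any(self.probs < 0) or np.any(self.background <= 0):
            raise ValueError("probabilities must be non-negative, background positive")
        row_sums = self.probs.sum(axis=1)
        if not np.allclose(row_sums, 1.0, atol=1e-9):
            # counts or unnormalized probabilities: normalize with pseudocount
            self.probs = (self.probs + 1e-6) / (self.probs + 1e-6).sum(
                axis=1, keepdims=True
            )
        self.probs = np.maximum(self.probs, 1e-6)
        self.probs /= self.probs.sum(axis=1, keepdims=True)
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")
        self.log_odds = np.log2(self.probs / self.background)

    def __len__(self) -> int:
        return self.probs.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @classmethod
    def from_consensus(cls, consensus: str, confidence: float = 0.95) -> "Pwm":
        """PWM from an unambiguous consensus: the consensus base gets
        ``confidence`` probability, the rest split evenly."""
        probs = np.full((len(consensus), 4), (1 - confidence) / 3.0)
        for i, base in enumerate(consensus.upper()):
            probs[i, _BASES.index(base)] = confidence
        return cls(probs)

    @classmethod
    def read_tsv(cls, path) -> "Pwm":
        """Read a 4-row (A/C/G/T) tab-delimited matrix of counts or probabilities."""
        df = pd.read_csv(path, sep="\t", header=None, index_col=0)
        df.index = [str(i).upper() for i in df.index]
        if sorted(df.index) != sorted(_BASES):
            raise ValueError("PWM file must have rows A, C, G, T")
        return cls(df.loc[list(_BASES)].to_numpy().T)

    def score(self, window: str) -> float:
        """Log-odds score of one L-length window (N scores as background)."""
        s = 0.0
        for i, base in enumerate(window.upper()):
            if base == "N":
                continue
            s += self.log_odds[i, _BASES.index(base)]
        return float(s)


@dataclass
class MotifScanResult:
    """Hits plus per-promoter presence from a two-strand PWM scan."""

    hits: pd.DataFrame  # gene_id, position, strand, score
    best: pd.DataFrame  # gene_id, best_score, n_hits, present
    threshold: float

    @property
    def n_present(self) -> int:
        return int(self.best["present"].sum())

    @property
    def present_genes(self) -> set[str]:
        return set(self.best.loc[self.best["present"], "gene_id"])


def scan_motif(
    pwm: Pwm,
    promoters: PromoterSet,
    threshold: float | None = None,
    threshold_fraction: float = 0.8,
) -> MotifScanResult:
    """Scan both strands of every promoter for PWM matches.

    A hit is a window whose log-odds score is >= the threshold (by
    default ``threshold_fraction`` of the maximum attainable score).
    Reported hit positions are on the promoter sequence as stored
    (5'->3' toward the gene); minus-strand hits come from scanning the
    reverse complement. Sequences with > 50% N are skipped with a warning.
    """
    if threshold is None:
        threshold = threshold_fraction * pwm.max_score
    L = len(pwm)
    hit_rows = []
    best_rows = []
    for gene, seq in promoters.sequences().items():
        if len(seq) < L:
            raise ValueError(f"promoter of {gene} shorter than the motif")
        if seq.count("N") > 0.5 * len(seq):
            warnings.warn(f"promoter of {gene} is >50% N; skipped", stacklevel=2)
            continue
        best = -np.inf
        n_hits = 0
        for strand, s in (("+", seq), ("-", seq.translate(_COMP)[::-1])):
            for pos in range(len(s) - L + 1):
                sc = pwm.score(s[pos : pos + L])
                fwd_pos = pos if strand == "+" else len(s) - L - pos
                if sc > best:
                    best = sc
                if sc >= threshold:
                    n_hits += 1
                    hit_rows.append(
                        {"gene_id": gene, "position": fwd_pos, "strand": strand, "score": sc}
                    )
        best_rows.append(
            {
                "gene_id": gene,
                "best_score": best,
                "n_hits": n_hits,
                "present": n_hits > 0,
            }
        )
    hits = pd.DataFrame(hit_rows, columns=["gene_id", "position", "strand", "score"])
    best = pd.DataFrame(best_rows, columns=["gene_id", "best_score", "n_hits", "present"])
    return MotifScanResult(hits=hits, best=best, threshold=float(threshold))


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
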