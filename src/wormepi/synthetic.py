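"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of its spec and seed (identical seeds
reproduce byte-identical files) and emits a machine-readable ground
truth alongside its data, so recovery tests compare against planted
truth rather than hard-coded numbers.

The statistical structure emulates the assays the pipeline targets:

* lifespans — Gompertz mortality (realistic worm survival curvature),
  cohorts of ~90 animals per replicate, a multiplicative time-scale
  shift planting a chosen percent mean-lifespan extension, and uniform
  censoring of a small fraction of animals (escapers);
* ChIP coverage — per-base Poisson depth for total H3 and for marks,
  with mark depth multiplied by an enrichment factor over the TSS
  +/- 1 kb of a planted gene subset in the treated condition only, so
  the H3-normalized ratio equals the planted factor by construction;
* RNA counts — negative-binomial counts with a planted up-regulated
  subset scaled by a fold change, plus a built-in two-group test that
  produces the differential-expression table the funnel consumes;
* promoters — background sequences at a stated base composition with a
  consensus motif planted once (random position and strand) in a chosen
  subset, the background scrubbed of chance exact occurrences so the
  planted subset is the exact truth;
* images — an elliptical cell outline, a Gaussian nuclear blob, and a
  signal channel that is absent, uniform, nuclear, or an annulus at a
  chosen normalized radius, under Poisson shot noise plus Gaussian read
  noise.

Child random streams are derived from the one global seed through
``numpy.random.SeedSequence(seed, spawn_key=(stream,))`` with a fixed
stream number per generator, so generators are independent and stable.
"""

from __future__ import annotations

import functools
import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .chipseq import CoverageTrack, GenomeAnnotation
from .integration import PromoterSet
from .radial import CellRoi, MicroscopyImage, _ray_boundary_distances
from .survival import LifespanExperiment, SurvivalCohort

__all__ = [
    "CohortSpec",
    "TrackSpec",
    "ExpressionSpec",
    "PromoterSpec",
    "ImageSpec",
    "gen_survival",
    "gen_genome_and_tracks",
    "gen_expression",
    "gen_promoters",
    "gen_image",
    "child_rng",
    "DEFAULT_CONSENSUS",
]

# stream numbers for SeedSequence spawn keys, one per generator
_STREAMS = {"survival": 1, "tracks": 2, "expression": 3, "promoters": 4, "image": 5}

# illustrative TF-binding consensus used by default in synthetic promoter
# scenarios; it is NOT a published SKN-1 matrix (real scans must supply one)
DEFAULT_CONSENSUS = "GCATTTATCATG"


def child_rng(seed: int, stream: int) -> np.random.Generator:
    """Independent generator for (seed, stream) under the documented scheme."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


# --------------------------------------------------------------------------
# lifespans
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSpec:
    """Conditions of a replicated lifespan assay.

    ``gompertz_shape`` controls mortality curvature (the scale is solved
    so the control mean hits ``control_mean_days``); the default shape
    gives a coefficient of variation around 0.25, typical of worm
    lifespan assays. ``extension_pct`` multiplies the treated time
    scale, planting that percent shift in mean lifespan.
    """

    n_per_replicate: int = 90
    n_replicates: int = 3
    control_mean_days: float = 20.0
    gompertz_shape: float = 0.001
    extension_pct: float = 35.0
    censor_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_replicate <= 0 or self.n_replicates <= 0:
            raise ValueError("cohort sizes must be positive")
        if not (0.0 <= self.censor_rate < 1.0):
            raise ValueError("censor_rate must be in [0, 1)")
        if self.extension_pct <= -100.0:
            raise ValueError("extension_pct must exceed -100")
        if self.gompertz_shape <= 0 or self.control_mean_days <= 0:
            raise ValueError("Gompertz parameters must be positive")


@functools.lru_cache(maxsize=32)
def _gompertz_unit_mean(shape: float) -> float:
    return float(sps.gompertz.mean(shape))


def _gompertz_days(
    rng: np.random.Generator, n: int, shape: float, mean_days: float
) -> np.ndarray:
    scale = mean_days / _gompertz_unit_mean(shape)
    t = sps.gompertz.rvs(shape, scale=scale, size=n, random_state=rng)
    return np.maximum(1.0, np.rint(t))


def gen_survival(spec: CohortSpec) -> tuple[LifespanExperiment, dict]:
    """Replicated treated/control cohorts with a planted extension."""
    rng = child_rng(spec.seed, _STREAMS["survival"])
    factor = 1.0 + spec.extension_pct / 100.0
    pairs = []
    for rep in range(1, spec.n_replicates + 1):
        cohorts = {}
        for cond, mean in (
            ("treated", spec.control_mean_days * factor),
            ("control", spec.control_mean_days),
        ):
            days = _gompertz_days(rng, spec.n_per_replicate, spec.gompertz_shape, mean)
            events = np.ones(days.size, dtype=bool)
            censor = rng.random(days.size) < spec.censor_rate
            if censor.any():
                c_days = np.maximum(
                    1.0, np.rint(rng.random(int(censor.sum())) * days[censor])
                )
                days = days.copy()
                days[censor] = c_days
                events[censor] = False
            cohorts[cond] = SurvivalCohort(days, events, condition=cond, replicate=str(rep))
        pairs.append((cohorts["treated"], cohorts["control"]))
    truth = {
        "extension_pct": spec.extension_pct,
        "control_mean_days": spec.control_mean_days,
        "gompertz_shape": spec.gompertz_shape,
        "censor_rate": spec.censor_rate,
        "n_per_replicate": spec.n_per_replicate,
        "n_replicates": spec.n_replicates,
        "seed": spec.seed,
    }
    return LifespanExperiment(pairs, label=f"planted+{spec.extension_pct:g}%"), truth


# --------------------------------------------------------------------------
# genome + ChIP coverage tracks
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TrackSpec:
    """Conditions of a synthetic ChIP experiment.

    Genes are laid out in equal slots on a 200 bp grid so the planted
    TSS +/- ``half_width`` enriched regions align exactly with the
    fixed differential windows — the planted-truth window set is then
    well defined. Mark depth is H3 depth times ``enrichment_factor``
    over enriched regions in the treated condition (x1 elsewhere), so
    the H3-normalized ratio carries the planted factor directly.
    """

    genome_length: int = 100_000
    chrom: str = "chrI"
    n_genes: int = 25
    gene_length: int = 800
    n_enriched: int = 3
    enrichment_factor: float = 3.0
    mean_depth: float = 30.0
    replicates: int = 3
    half_width: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.enrichment_factor <= 0 or self.mean_depth <= 0:
            raise ValueError("enrichment factor and depth must be positive")
        if self.n_enriched > self.n_genes:
            raise ValueError("enriched genes must be a subset of the gene universe")
        slot = self.genome_length // self.n_genes
        if slot < self.gene_length + 2 * self.half_width + 400:
            raise ValueError(
                f"{self.n_genes} genes do not fit in {self.genome_length} bp "
                "with non-overlapping TSS windows"
            )


def gen_genome_and_tracks(
    spec: TrackSpec,
) -> tuple[GenomeAnnotation, dict[str, str], dict, dict]:
    """Annotation, genome FASTA dict, coverage tracks, and planted truth.

    Tracks are keyed ``(mark, condition, replicate)`` with marks
    'H3K79me2', 'H3K79me3' and 'H3', conditions 'treated' and 'control'
    and replicates '1'..'R'.
    """
    rng = child_rng(spec.seed, _STREAMS["tracks"])
    slot = spec.genome_length // spec.n_genes
    grid = 200
    rows = []
    for i in range(spec.n_genes):
        start = i * slot + 1000
        start -= start % grid  # keep TSS on the window grid
        end = start + spec.gene_length
        strand = "+" if rng.random() < 0.5 else "-"
        rows.append(
            {
                "gene_id": f"g{i + 1:04d}",
                "chrom": spec.chrom,
                "start": int(start),
                "end": int(end),
                "strand": strand,
            }
        )
    ann = GenomeAnnotation(pd.DataFrame(rows))
    enriched = sorted(
        rng.choice(ann.genes["gene_id"], size=spec.n_enriched, replace=False)
    )
    tss = ann.tss()
    regions = [
        (max(0, int(tss[g]) - spec.half_width), min(spec.genome_length, int(tss[g]) + spec.half_width))
        for g in enriched
    ]
    factor_map = np.ones(spec.genome_length)
    for lo, hi in regions:
        factor_map[lo:hi] = spec.enrichment_factor

    seq = "".join(rng.choice(list("ACGT"), size=spec.genome_length, p=[0.32, 0.18, 0.18, 0.32]))
    genome = {spec.chrom: seq}

    tracks: dict[tuple[str, str, str], CoverageTrack] = {}
    for cond in ("treated", "control"):
        cond_factor = factor_map if cond == "treated" else np.ones(spec.genome_length)
        for rep in range(1, spec.replicates + 1):
            h3 = rng.poisson(spec.mean_depth, spec.genome_length).astype(float)
            tracks[("H3", cond, str(rep))] = CoverageTrack(
                {spec.chrom: h3}, mark="H3", condition=cond, replicate=str(rep)
            )
            for mark in ("H3K79me2", "H3K79me3"):
                mk = rng.poisson(spec.mean_depth * cond_factor).astype(float)
                tracks[(mark, cond, str(rep))] = CoverageTrack(
                    {spec.chrom: mk}, mark=mark, condition=cond, replicate=str(rep)
                )

    window = grid
    enriched_windows = sorted(
        {w for lo, hi in regions for w in range(lo // window, math.ceil(hi / window))}
    )
    truth = {
        "enriched_genes": [str(g) for g in enriched],
        "enriched_regions": regions,
        "enriched_windows": enriched_windows,
        "window": window,
        "enrichment_factor": spec.enrichment_factor,
        "seed": spec.seed,
    }
    return ann, genome, tracks, truth


# --------------------------------------------------------------------------
# expression counts
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpressionSpec:
    """Conditions of a synthetic RNA count experiment."""

    gene_ids: tuple[str, ...] = tuple(f"g{i + 1:04d}" for i in range(200))
    planted_up: tuple[str, ...] = ()
    fold_change: float = 4.0
    nb_mean: float = 100.0
    dispersion: float = 0.1
    n_per_condition: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fold_change <= 0 or self.nb_mean <= 0 or self.dispersion <= 0:
            raise ValueError("fold change, mean and dispersion must be positive")
        if not set(self.planted_up) <= set(self.gene_ids):
            raise ValueError("planted genes must be in the gene universe")


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, disp: float) -> np.ndarray:
    n = 1.0 / disp
    p = n / (n + mu)
    return rng.negative_binomial(n, p)


def gen_expression(spec: ExpressionSpec) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """NB counts, the derived DE table, and planted truth.

    The DE table is produced by the built-in two-group test: a Welch
    t-test on log2(count + 1) per gene, BH-adjusted, with the linear
    fold change estimated from condition means.
    """
    from .stats import bh_fdr, welch_t_test

    rng = child_rng(spec.seed, _STREAMS["expression"])
    genes = list(spec.gene_ids)
    n = spec.n_per_condition
    up = set(spec.planted_up)
    mu = np.full(len(genes), spec.nb_mean)
    mu_t = np.where([g in up for g in genes], mu * spec.fold_change, mu)
    counts = {}
    for i in range(n):
        counts[f"treated_{i + 1}"] = _nb_counts(
            rng, np.broadcast_to(mu_t, mu_t.shape), spec.dispersion
        )
    for i in range(n):
        counts[f"control_{i + 1}"] = _nb_counts(
            rng, np.broadcast_to(mu, mu.shape), spec.dispersion
        )
    table = pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"))

    tre = table.filter(like="treated_").to_numpy(float)
    ctl = table.filter(like="control_").to_numpy(float)
    ps = np.array(
        [
            welch_t_test(np.log2(tre[i] + 1), np.log2(ctl[i] + 1)).p
            for i in range(len(genes))
        ]
    )
    fc = (tre.mean(axis=1) + 0.5) / (ctl.mean(axis=1) + 0.5)
    de = pd.DataFrame(
        {"gene_id": genes, "fc": fc, "p": ps, "q": bh_fdr(ps)}
    )
    truth = {
        "planted_up": sorted(up),
        "fold_change": spec.fold_change,
        "seed": spec.seed,
    }
    return table, de, truth


# --------------------------------------------------------------------------
# promoters
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PromoterSpec:
    """Conditions of a synthetic promoter/motif scan scenario.

    Base composition defaults to an AT-rich genome (32% A/T each). The
    consensus is planted exactly once per chosen promoter at a random
    recorded position and strand; background sequence is scrubbed of
    chance exact occurrences of the consensus (or its reverse
    complement) so presence truth is the planted subset, exactly.
    """

    n_promoters: int = 36
    length: int = 1000
    n_planted: int = 18
    consensus: str = DEFAULT_CONSENSUS
    at_fraction: float = 0.64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_planted > self.n_promoters:
            raise ValueError("planted subset must fit in the promoter set")
        if self.length < len(self.consensus):
            raise ValueError("motif longer than the promoter")
        if not set(self.consensus.upper()) <= set("ACGT"):
            raise ValueError("consensus must be unambiguous A/C/G/T")


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _background_seq(rng: np.random.Generator, length: int, at: float, forbidden: list[str]) -> str:
    p = [at / 2, (1 - at) / 2, (1 - at) / 2, at / 2]  # A C G T
    seq = "".join(rng.choice(list("ACGT"), size=length, p=p))
    # scrub chance exact occurrences of the consensus on either strand
    for _ in range(100):
        pos = min(
            (seq.find(f) for f in forbidden if seq.find(f) >= 0), default=-1
        )
        if pos < 0:
            return seq
        k = len(forbidden[0])
        patch = "".join(rng.choice(list("ACGT"), size=k, p=p))
        seq = seq[:pos] + patch + seq[pos + k :]
    raise RuntimeError("could not scrub consensus from background sequence")


def gen_promoters(spec: PromoterSpec) -> tuple[PromoterSet, dict]:
    """Promoter set with the consensus planted in a recorded subset."""
    rng = child_rng(spec.seed, _STREAMS["promoters"])
    cons = spec.consensus.upper()
    forbidden = [cons, _revcomp(cons)]
    names = [f"p{i + 1:03d}" for i in range(spec.n_promoters)]
    planted = sorted(rng.choice(names, size=spec.n_planted, replace=False))
    rows = []
    placements = {}
    for name in names:
        seq = _background_seq(rng, spec.length, spec.at_fraction, forbidden)
        if name in planted:
            pos = int(rng.integers(0, spec.length - len(cons) + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            ins = cons if strand == "+" else _revcomp(cons)
            seq = seq[:pos] + ins + seq[pos + len(cons) :]
            placements[name] = {"position": pos, "strand": strand}
        rows.append(
            {
                "gene_id": name,
                "chrom": "synthetic",
                "start": 0,
                "end": spec.length,
                "strand": "+",
                "span": spec.length + 1,
                "sequence": seq,
            }
        )
    truth = {
        "planted": list(planted),
        "placements": placements,
        "consensus": cons,
        "seed": spec.seed,
    }
    return PromoterSet(pd.DataFrame(rows)), truth


# --------------------------------------------------------------------------
# images
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ImageSpec:
    """Conditions of a synthetic single-cell image.

    The cell is an ellipse (optionally rotated) sampled as a 72-vertex
    polygon; the nucleus a Gaussian blob offset from the cell center.
    The signal channel follows ``pattern``: 'absent' (background only),
    'uniform', 'nuclear' (co-located with the nucleus), or
    'ring' (annulus at normalized radius ``ring_r0`` of width
    ``ring_width``). Photon noise is Poisson on the clean image plus
    Gaussian read noise.
    """

    shape: tuple[int, int] = (160, 160)
    cell_center: tuple[float, float] = (80.0, 80.0)  # (x, y)
    semi_axes: tuple[float, float] = (55.0, 40.0)
    rotation_deg: float = 20.0
    n_vertices: int = 72
    nucleus_offset: tuple[float, float] = (8.0, -6.0)
    nucleus_sigma: float = 6.0
    nucleus_amplitude: float = 150.0
    pattern: str = "ring"
    amplitude: float = 80.0
    ring_r0: float = 0.5
    ring_width: float = 0.06
    background: float = 20.0
    read_noise: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pattern not in {"absent", "uniform", "nuclear", "ring"}:
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if not (0.0 < self.ring_r0 < 1.0):
            raise ValueError("ring_r0 must be in (0, 1)")
        # the nucleus center must fall inside the cell ellipse
        dx, dy = self.nucleus_offset
        a, b = self.semi_axes
        th = math.radians(self.rotation_deg)
        u = dx * math.cos(th) + dy * math.sin(th)
        v = -dx * math.sin(th) + dy * math.cos(th)
        if (u / a) ** 2 + (v / b) ** 2 >= 1.0:
            raise ValueError("nucleus center lies outside the cell outline")


def _ellipse_polygon(spec: ImageSpec) -> np.ndarray:
    t = np.linspace(0, 2 * np.pi, spec.n_vertices, endpoint=False)
    a, b = spec.semi_axes
    th = math.radians(spec.rotation_deg)
    x = a * np.cos(t)
    y = b * np.sin(t)
    xr = x * math.cos(th) - y * math.sin(th) + spec.cell_center[0]
    yr = x * math.sin(th) + y * math.cos(th) + spec.cell_center[1]
    return np.column_stack([xr, yr])


def gen_image(
    spec: ImageSpec, cell_id: str = "cell", condition: str = "", replicate: str = "1"
) -> tuple[MicroscopyImage, CellRoi, dict]:
    """Two-channel image ('dapi', 'signal'), its ROI polygon, and truth."""
    rng = child_rng(spec.seed, _STREAMS["image"])
    h, w = spec.shape
    yy, xx = np.mgrid[0:h, 0:w]
    verts = _ellipse_polygon(spec)
    roi = CellRoi(verts, cell_id=cell_id, position=condition, replicate=replicate)
    nx = spec.cell_center[0] + spec.nucleus_offset[0]
    ny = spec.cell_center[1] + spec.nucleus_offset[1]
    d2 = (xx - nx) ** 2 + (yy - ny) ** 2
    dapi = 5.0 + spec.nucleus_amplitude * np.exp(-d2 / (2 * spec.nucleus_sigma**2))

    signal = np.full(spec.shape, spec.background, dtype=float)
    mask = roi.mask(spec.shape)
    if spec.pattern == "uniform":
        signal[mask] += spec.amplitude
    elif spec.pattern == "nuclear":
        signal += spec.amplitude * np.exp(-d2 / (2 * spec.nucleus_sigma**2))
    elif spec.pattern == "ring":
        rows, cols = np.nonzero(mask)
        pts = np.column_stack([cols, rows]).astype(float)
        center = np.array([nx, ny])
        dist = np.linalg.norm(pts - center, axis=1)
        bound = _ray_boundary_distances(center, pts, verts)
        r = np.where(dist > 0, dist / bound, 0.0)
        signal[rows, cols] += spec.amplitude * np.exp(
            -((r - spec.ring_r0) ** 2) / (2 * spec.ring_width**2)
        )
    noisy = {
        "dapi": rng.poisson(dapi) + rng.normal(0, spec.read_noise, spec.shape),
        "signal": rng.poisson(signal) + rng.normal(0, spec.read_noise, spec.shape),
    }
    channels = {k: np.maximum(v, 0.0) for k, v in noisy.items()}
    img = MicroscopyImage(channels)
    truth = {
        "nucleus_center": [nx, ny],
        "pattern": spec.pattern,
        "ring_r0": spec.ring_r0,
        "ring_width": spec.ring_width,
        "amplitude": spec.amplitude,
        "background": spec.background,
        "seed": spec.seed,
    }
    return img, roi, truth


def write_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True, default=str)
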