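"""Config-driven, reproducible end-to-end runs.

A run is described by one flat YAML/dict config (unknown keys are
fatal — no silent typos), executes a selected subset of stages into an
output directory, and writes a manifest recording package version,
parameters and SHA-256 digests of every output table. Two runs of the
same config are digest-identical: every source of randomness derives
from the config seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from importlib import metadata
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chipseq, integration, radial, survival, synthetic

log = logging.getLogger("wormepi")

STAGES = ("survival", "chip", "integrate", "radial")

_ALLOWED_TOP = {"seed", "out_dir", "stages", "survival", "chip", "integrate", "radial"}


def _spec_params(cls, params: dict, seed: int, extra: set[str] = frozenset()):
    allowed = {f.name for f in dataclasses.fields(cls)} | extra
    unknown = set(params) - allowed
    if unknown:
        raise ValueError(f"unknown config key(s) for {cls.__name__}: {sorted(unknown)}")
    return params


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run(config: dict, out_dir: str | Path | None = None) -> Path:
    """Execute the configured stages; returns the run directory."""
    unknown = set(config) - _ALLOWED_TOP
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    seed = int(config.get("seed", 0))
    out = Path(out_dir or config.get("out_dir", "wormepi_run"))
    out.mkdir(parents=True, exist_ok=True)
    stages = config.get("stages", list(STAGES))
    bad = set(stages) - set(STAGES)
    if bad:
        raise ValueError(f"unknown stage(s): {sorted(bad)}")
    outputs: list[Path] = []
    for stage in stages:
        fn = {"survival": _stage_survival, "chip": _stage_chip,
              "integrate": _stage_integrate, "radial": _stage_radial}[stage]
        log.info("running stage %s", stage)
        outputs += fn(config.get(stage) or {}, seed, out)
    manifest = {
        "package": "wormepi",
        "version": metadata.version("wormepi") if _installed() else "dev",
        "seed": seed,
        "stages": list(stages),
        "parameters": {s: config.get(s) or {} for s in stages},
        "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def _installed() -> bool:
    try:
        metadata.version("wormepi")
        return True
    except metadata.PackageNotFoundError:
        return False


def _stage_survival(params: dict, seed: int, out: Path) -> list[Path]:
    params = dict(_spec_params(synthetic.CohortSpec, params, seed, extra={"input"}))
    input_path = params.pop("input", None)
    if input_path:
        exp = survival.read_lifespan_tsv(input_path)
    else:
        spec = synthetic.CohortSpec(**{**params, "seed": seed})
        exp, truth = synthetic.gen_survival(spec)
        synthetic.write_truth(truth, out / "survival_truth.json")
        survival.write_lifespan_tsv(exp, out / "lifespans.tsv")
    summary = survival.combined_lifespan_test(exp)
    report = survival.lifespan_report([summary])
    _write_tsv(report, out / "lifespan_report.tsv")
    km_rows = []
    for t_coh, c_coh in exp.replicates:
        for coh in (t_coh, c_coh):
            km = survival.kaplan_meier(coh).as_frame()
            km.insert(0, "replicate", coh.replicate)
            km.insert(0, "condition", coh.condition)
            km_rows.append(km)
    _write_tsv(pd.concat(km_rows, ignore_index=True), out / "km_curves.tsv")
    made = [out / "lifespan_report.tsv", out / "km_curves.tsv"]
    if not input_path:
        made += [out / "lifespans.tsv", out / "survival_truth.json"]
    return made


def _chip_ratio_tracks(params: dict, seed: int, out: Path | None):
    spec = synthetic.TrackSpec(
        **{**_spec_params(synthetic.TrackSpec, params, seed), "seed": seed}
    )
    ann, genome, tracks, truth = synthetic.gen_genome_and_tracks(spec)
    pseudocount = 0.5
    ratios: dict[str, dict[str, list]] = {}
    for mark in ("H3K79me2", "H3K79me3"):
        ratios[mark] = {"treated": [], "control": []}
        for cond in ("treated", "control"):
            for rep in range(1, spec.replicates + 1):
                ratios[mark][cond].append(
                    chipseq.normalize_mark_to_h3(
                        tracks[(mark, cond, str(rep))],
                        tracks[("H3", cond, str(rep))],
                        pseudocount=pseudocount,
                    )
                )
    return spec, ann, genome, tracks, ratios, truth


def _stage_chip(params: dict, seed: int, out: Path) -> list[Path]:
    diff_keys = {"window", "p_max", "q_max", "min_log2fc"}
    spec_params = {k: v for k, v in params.items() if k not in diff_keys}
    diff_params = {k: v for k, v in params.items() if k in diff_keys}
    spec, ann, genome, tracks, ratios, truth = _chip_ratio_tracks(spec_params, seed, out)
    ann.write_bed(out / "genes.bed")
    integration.write_fasta(genome, out / "genome.fa")
    synthetic.write_truth(truth, out / "chip_truth.json")
    for (mark, cond, rep), tr in tracks.items():
        tr.to_bedgraph(out / f"{mark}_{cond}_rep{rep}.bedGraph")
    made = [out / "genes.bed", out / "genome.fa", out / "chip_truth.json"]
    made += sorted(out.glob("*.bedGraph"))
    for mark in ("H3K79me2", "H3K79me3"):
        mats = {
            cond: chipseq.tss_signal_matrix(
                _mean_track(ratios[mark][cond]), ann
            )
            for cond in ("treated", "control")
        }
        cmp_ = chipseq.metaprofile_compare(mats["treated"], mats["control"])
        curve = pd.DataFrame(
            {
                "bin_center_bp": mats["treated"].bin_centers(),
                "treated_mean": cmp_.curve_a,
                "control_mean": cmp_.curve_b,
            }
        )
        _write_tsv(curve, out / f"{mark}_metaprofile.tsv")
        diff = chipseq.call_differential_windows(
            ratios[mark]["treated"], ratios[mark]["control"], **diff_params
        )
        _write_tsv(diff, out / f"{mark}_diffwindows.tsv")
        made += [out / f"{mark}_metaprofile.tsv", out / f"{mark}_diffwindows.tsv"]
    return made


def _mean_track(tracks: list[chipseq.CoverageTrack]) -> chipseq.CoverageTrack:
    chroms = tracks[0].depth.keys()
    return chipseq.CoverageTrack(
        {c: np.mean([t.depth[c] for t in tracks], axis=0) for c in chroms},
        mark=tracks[0].mark,
        condition=tracks[0].condition,
    )


def _stage_integrate(params: dict, seed: int, out: Path) -> list[Path]:
    allowed = {
        "chip", "fold_change", "n_up_extra", "fc_min", "p_max", "q_max",
        "promoter_upstream", "n_promoters", "promoter_length", "n_planted",
        "consensus", "threshold_fraction",
    }
    unknown = set(params) - allowed
    if unknown:
        raise ValueError(f"unknown config key(s) for integrate: {sorted(unknown)}")
    spec, ann, genome, tracks, ratios, truth = _chip_ratio_tracks(
        params.get("chip") or {}, seed, None
    )
    calls = {}
    for mark in ("H3K79me2", "H3K79me3"):
        diff = chipseq.call_differential_windows(
            ratios[mark]["treated"], ratios[mark]["control"]
        )
        calls[mark] = integration.map_sites_to_genes(diff, ann, mark=mark)
    both, venn = integration.intersect_mark_sets(calls["H3K79me2"], calls["H3K79me3"])

    planted_up = sorted(truth["enriched_genes"])
    expr_spec = synthetic.ExpressionSpec(
        gene_ids=tuple(ann.genes["gene_id"]),
        planted_up=tuple(planted_up),
        fold_change=float(params.get("fold_change", 4.0)),
        seed=seed,
    )
    counts, de, expr_truth = synthetic.gen_expression(expr_spec)
    filt = integration.CandidateFilter(
        fc_min=float(params.get("fc_min", 1.5)),
        p_max=float(params.get("p_max", 0.01)),
        q_max=float(params.get("q_max", 0.05)),
    )
    up = integration.filter_upregulated(de, filt)
    cands = integration.select_candidates(
        both, up, de=de, calls_me2=calls["H3K79me2"], calls_me3=calls["H3K79me3"]
    )
    _write_tsv(de, out / "de_table.tsv")
    _write_tsv(cands, out / "candidates.tsv")
    (out / "venn.json").write_text(json.dumps(venn, indent=2, sort_keys=True))

    prom_spec = synthetic.PromoterSpec(
        n_promoters=int(params.get("n_promoters", 36)),
        length=int(params.get("promoter_length", 1000)),
        n_planted=int(params.get("n_planted", 18)),
        consensus=str(params.get("consensus", synthetic.DEFAULT_CONSENSUS)),
        seed=seed,
    )
    promoters, prom_truth = synthetic.gen_promoters(prom_spec)
    pwm = integration.Pwm.from_consensus(prom_spec.consensus)
    scan = integration.scan_motif(
        pwm, promoters, threshold_fraction=float(params.get("threshold_fraction", 0.8))
    )
    integration.write_fasta(promoters.sequences(), out / "promoters.fa")
    _write_tsv(scan.hits, out / "motif_hits.tsv")
    _write_tsv(scan.best, out / "motif_presence.tsv")
    synthetic.write_truth(prom_truth, out / "promoter_truth.json")
    return [
        out / "de_table.tsv", out / "candidates.tsv", out / "venn.json",
        out / "promoters.fa", out / "motif_hits.tsv", out / "motif_presence.tsv",
        out / "promoter_truth.json",
    ]


def _stage_radial(params: dict, seed: int, out: Path) -> list[Path]:
    allowed = {"n_cells", "n_replicates", "n_bins", "ring_r0", "amplitude"}
    unknown = set(params) - allowed
    if unknown:
        raise ValueError(f"unknown config key(s) for radial: {sorted(unknown)}")
    n_cells = int(params.get("n_cells", 4))
    n_reps = int(params.get("n_replicates", 2))
    n_bins = int(params.get("n_bins", 20))
    profiles = []
    i = 0
    for cond, pattern in (("treated", "ring"), ("control", "uniform")):
        for rep in range(1, n_reps + 1):
            for _ in range(n_cells):
                spec = synthetic.ImageSpec(
                    pattern=pattern,
                    ring_r0=float(params.get("ring_r0", 0.5)),
                    amplitude=float(params.get("amplitude", 80.0)),
                    seed=seed * 100_000 + i,
                )
                img, roi, truth = synthetic.gen_image(
                    spec, cell_id=f"{cond}_r{rep}_c{i}", condition=cond,
                    replicate=str(rep),
                )
                center = radial.detect_nucleus_center(img, roi)
                profiles.append(
                    radial.radial_profile(img, roi, center, n_bins=n_bins)
                )
                i += 1
    _write_tsv(radial.profiles_to_frame(profiles), out / "radial_profiles.tsv")
    curves = radial.aggregate_profiles(profiles)
    _write_tsv(curves, out / "radial_group_curves.tsv")
    rel = radial.normalize_to_control(
        curves[curves["condition"] == "treated"],
        curves[curves["condition"] == "control"],
    )
    _write_tsv(rel, out / "radial_relative.tsv")
    omnibus, per_bin = radial.compare_profile_groups(profiles)
    _write_tsv(per_bin, out / "radial_per_bin_stats.tsv")
    return [
        out / "radial_profiles.tsv", out / "radial_group_curves.tsv",
        out / "radial_relative.tsv", out / "radial_per_bin_stats.tsv",
    ]
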