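"""End-to-end orchestration: simulation -> normalization -> SAM -> annotation
-> enrichment -> quantitative validation, with a manifest and JSON report.

Each stage draws its randomness from a seed derived deterministically from the
master seed and the stage name, so a rerun with the same configuration is
bit-identical while stages stay statistically independent.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation as anno
from . import enrichment as enr
from . import normalize as norm
from . import quant
from . import sam
from . import synthetic as syn
from .regions import write_bed

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "stage_seed"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved."""


def stage_seed(master: int, name: str) -> int:
    """Derive a per-stage seed from the master seed and the stage name."""
    digest = hashlib.sha256(f"{master}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """Every knob of a full synthetic-mode run, with study defaults.

    Defaults mirror the modelled analysis where it states them: NormExp offset
    50, FDR target 5%, 1,000 permutations, promoter window -2000/+500, motif
    GAGGAA, blast-count stage thresholds 20/50.
    """

    out_dir: str = "methprog_run"
    seed: int = 0
    sim: syn.SimConfig = field(default_factory=syn.SimConfig)
    offset: float = 50.0
    loess_span: float = 0.4
    rank_tol: float = 0.05
    fdr_target: float = 0.05
    sam_B: int = 1000
    enrich_B: int = 1000
    motif: str = "GAGGAA"
    both_strands: bool = False
    min_probes_stringent: int = 2
    n_amplicons: int = 10
    bootstrap_B: int = 1000
    massarray_noise_sd: float = 0.05
    massarray_missing_rate: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.fdr_target < 1:
            raise ValueError("FDR target must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", {})
        cfg = cls(**raw)
        cfg.sim = syn.SimConfig(**sim_raw)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return inner

    return wrap


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full synthetic analysis; returns the report dictionary.

    Writes every intermediate artifact plus ``report.json`` (per-stage DMP
    counts, Venn partition, feature distribution, enrichment and validation
    results, recovery metrics against the generator truth) and
    ``manifest.json`` (config hash, derived seeds, declared outputs).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    fh = logging.FileHandler(out / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("methprog")
    root.addHandler(fh)
    try:
        report = _run(config, out, written)
    finally:
        root.removeHandler(fh)
        fh.close()
    return report


def _write(df: pd.DataFrame, path: Path, written: list[str]) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    written.append(path.name)


def _run(config: PipelineConfig, out: Path, written: list[str]) -> dict:
    seeds = {
        name: stage_seed(config.seed, name)
        for name in ("reference", "cohort", "sam", "enrichment", "massarray", "quant")
    }

    # --- simulate -----------------------------------------------------------
    simulate = _stage("simulate")(_simulate)
    ref, samples, design = simulate(config, seeds, out, written)

    # --- normalize ----------------------------------------------------------
    normalize = _stage("normalize")(_normalize)
    ma = normalize(config, ref, samples, out, written)

    # --- SAM per stage ------------------------------------------------------
    sam_stage = _stage("sam")(_sam)
    results, venn = sam_stage(config, seeds, ma, samples, out, written)

    # --- annotation ---------------------------------------------------------
    annotate = _stage("annotate")(_annotate)
    features, gene_calls = annotate(config, ref, results, out, written)

    # --- enrichment ---------------------------------------------------------
    enrich = _stage("enrich")(_enrich)
    enrichment_report = enrich(config, seeds, ref, results, out, written)

    # --- quantitative validation -------------------------------------------
    validate = _stage("quant")(_quant)
    quant_report = validate(config, seeds, ref, design, ma, samples, out, written)

    # --- report -------------------------------------------------------------
    truth_eval = _truth_eval(ref, results)
    report = {
        "stages": list(results),
        "n_probes": len(ref.probes),
        "n_cgis": len(ref.cgis),
        "dmp_counts": {
            st: {
                "hyper": len(r.hyper_ids),
                "hypo": len(r.hypo_ids),
                "delta": r.delta,
                "pi0": r.pi0,
                "s0": r.s0,
            }
            for st, r in results.items()
        },
        "venn": {
            "hyper": venn.counts("hyper"),
            "hypo": venn.counts("hypo"),
        },
        "feature_distribution": features["feature"].value_counts().to_dict(),
        "gene_calls": {
            st: {
                "min1_hyper": len(gc[1].called("hyper")),
                "min2_hyper": len(gc[2].called("hyper")),
            }
            for st, gc in gene_calls.items()
        },
        "enrichment": enrichment_report,
        "validation": quant_report,
        "truth_eval": truth_eval,
    }
    with open(out / "report.json", "w") as fhj:
        json.dump(report, fhj, indent=1, sort_keys=True, default=_json_default)
    written.append("report.json")

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "master_seed": config.seed,
        "stage_seeds": seeds,
        "outputs": sorted(set(written) | {"manifest.json", "run.log"}),
    }
    with open(out / "manifest.json", "w") as fhm:
        json.dump(manifest, fhm, indent=1, sort_keys=True, default=_json_default)
    return report


def _truth_eval(ref, results) -> dict:
    """Sensitivity and false-discovery proportion of each stage's calls
    against the generator's planted probe sets."""
    out = {}
    for st, res in results.items():
        truth_hyper = set(ref.truth.planted_hyper[st])
        truth_hypo = set(ref.truth.planted_hypo[st])
        ev = {}
        for direction, called, truth in (
            ("hyper", res.hyper_ids, truth_hyper),
            ("hypo", res.hypo_ids, truth_hypo),
        ):
            tp = len(called & truth)
            ev[direction] = {
                "n_called": len(called),
                "n_planted": len(truth),
                "sensitivity": tp / len(truth) if truth else float("nan"),
                "fdp": (len(called) - tp) / len(called) if called else 0.0,
            }
        out[st] = ev
    return out


def _simulate(config, seeds, out, written):
    ref = syn.simulate_reference(config.sim, seed=seeds["reference"])
    syn.write_reference(ref, out)
    written += [
        "genome.fa", "cgis.bed", "probes.bed", "probes.tsv", "peaks.bed",
        "genes.tsv", "chrom_sizes.tsv", "truth.json",
    ]
    design = syn.default_design()
    samples = syn.simulate_cohort(ref, design, seed=seeds["cohort"])
    _write(syn.cohort_frame(ref, samples), out / "intensities.tsv", written)
    return ref, samples, design


def _normalize(config, ref, samples, out, written):
    negctrl = ref.negctrl_mask
    m_cols, a_cols = {}, {}
    for s in samples:
        m, a = norm.normalize_pair(
            s.R, s.G, negctrl, config.offset, config.loess_span, config.rank_tol
        )
        m_cols[s.sample_id], a_cols[s.sample_id] = m, a
    ma = norm.MAMatrix(
        M=pd.DataFrame(m_cols, index=ref.probe_ids),
        A=pd.DataFrame(a_cols, index=ref.probe_ids),
        negctrl_mask=negctrl,
    )
    long = ma.M.stack().rename("M").to_frame()
    long["A"] = ma.A.stack()
    long = long.reset_index(names=["probe_id", "sample_id"])
    _write(long, out / "ma_matrix.tsv", written)
    return ma


def _sam(config, seeds, ma, samples, out, written):
    stages = {}
    for s in samples:
        stages.setdefault(s.stage, []).append(s.sample_id)
    results = {}
    for st in sam.STAGES:
        if st not in stages:
            continue
        m_stage = ma.M[stages[st]]
        res = sam.call_dmps(
            m_stage,
            fdr_target=config.fdr_target,
            B=config.sam_B,
            seed=stage_seed(seeds["sam"], st),
        )
        results[st] = res
        calls = pd.DataFrame(
            {
                "probe_id": res.d.index,
                "d": res.d.values,
                "called": [
                    p in res.hyper_ids or p in res.hypo_ids for p in res.d.index
                ],
                "direction": [
                    "hyper" if p in res.hyper_ids
                    else "hypo" if p in res.hypo_ids
                    else ""
                    for p in res.d.index
                ],
            }
        )
        _write(calls, out / f"sam_{st}.tsv", written)
        _write(res.fdr_table, out / f"fdr_table_{st}.tsv", written)
    venn = sam.stage_set_ops(results)
    with open(out / "venn.json", "w") as fh:
        json.dump(
            {
                "hyper": {"+".join(k): sorted(v) for k, v in venn.hyper_partition.items()},
                "hypo": {"+".join(k): sorted(v) for k, v in venn.hypo_partition.items()},
            },
            fh,
            indent=1,
            sort_keys=True,
        )
    written.append("venn.json")
    return results, venn


def _annotate(config, ref, results, out, written):
    features = anno.annotate_probes(ref.probes, ref.genes)
    _write(features, out / "probe_features.tsv", written)
    gene_calls = {}
    for st, res in results.items():
        gene_calls[st] = {
            k: anno.aggregate_genes(res.hyper_ids, res.hypo_ids, ref.probes, k)
            for k in (1, config.min_probes_stringent)
        }
        _write(
            gene_calls[st][1].table, out / f"gene_calls_{st}.tsv", written
        )
    return features, gene_calls


def _hyper_cgis(ref, res, min_probes=1):
    support: dict[str, int] = {}
    for p in ref.probes:
        if p.cgi_id and p.probe_id in res.hyper_ids:
            support[p.cgi_id] = support.get(p.cgi_id, 0) + 1
    by_name = ref.cgi_by_name()
    cgis = [by_name[nm] for nm in sorted(support) if support[nm] >= min_probes]
    return cgis, support


def _enrich(config, seeds, ref, results, out, written):
    res = results["preleukemic"]
    hyper1, support = _hyper_cgis(ref, res, 1)
    report = {}

    perm = enr.permutation_enrichment(
        ref.peaks, hyper1, ref.chrom_sizes, B=config.enrich_B,
        seed=stage_seed(seeds["enrichment"], "peaks"),
    )
    fisher = enr.cgi_peak_enrichment(hyper1, ref.cgis, ref.peaks, 1, support)
    fisher2 = enr.cgi_peak_enrichment(
        hyper1, ref.cgis, ref.peaks, config.min_probes_stringent, support
    )
    report["peaks"] = {
        "permutation": perm.to_dict(),
        "fisher_min1": fisher.to_dict(),
        f"fisher_min{config.min_probes_stringent}": fisher2.to_dict(),
    }

    sites = enr.scan_motif(ref.genome, config.motif, config.both_strands)
    write_bed(sites, out / "motif_sites.bed")
    written.append("motif_sites.bed")
    motif_perm = enr.permutation_enrichment(
        sites, hyper1, ref.chrom_sizes, B=config.enrich_B,
        seed=stage_seed(seeds["enrichment"], "motif"),
    )
    report["motif"] = {
        "motif": config.motif,
        "n_sites": len(sites),
        "in_hyper_cgis": motif_perm.observed,
        "permutation": motif_perm.to_dict(),
    }
    with open(out / "enrichment.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=_json_default)
    written.append("enrichment.json")
    return report


def _quant(config, seeds, ref, design, ma, samples, out, written):
    # amplicons: a mix of preleukemic-planted and unplanted islands
    planted = ref.truth.hyper_cgis["preleukemic"]
    unplanted = [
        c.name
        for c in ref.cgis
        if c.name not in set().union(*ref.truth.hyper_cgis.values())
        and c.name not in set().union(*ref.truth.hypo_cgis.values())
    ]
    n_p = min(len(planted), max(1, config.n_amplicons * 2 // 3))
    n_u = min(len(unplanted), config.n_amplicons - n_p)
    amplicons = [(f"amp{i + 1:02d}", nm) for i, nm in enumerate(planted[:n_p] + unplanted[:n_u])]
    table = syn.simulate_massarray(
        ref, design, amplicons, seed=seeds["massarray"],
        noise_sd=config.massarray_noise_sd,
        missing_rate=config.massarray_missing_rate,
    )
    long = table.values.stack(future_stack=True).rename("methylation_pct").to_frame() * 100
    long = long.reset_index(names=["sample_id", "cpg_unit"])
    long["group"] = long["sample_id"].map(table.sample_group)
    long["amplicon"] = long["cpg_unit"].map(table.unit_amplicon)
    _write(long, out / "amplicons.tsv", written)

    means = quant.amplicon_means(table)
    _write(means.reset_index(names="sample_id"), out / "means.tsv", written)

    groups = table.sample_group
    tests = []
    for st in sam.STAGES:
        kd = means.loc[groups[groups == st].index]
        wt = means.loc[groups[groups == "wildtype"].index]
        for amp in means.columns:
            a = kd[amp].dropna().values
            b = wt[amp].dropna().values
            if a.size < 2 or b.size < 2:
                continue
            u, p = quant.mann_whitney(a, b)
            tests.append(
                {"amplicon": amp, "groupA": st, "groupB": "wildtype", "U": u, "p": p}
            )
    tests_df = pd.DataFrame(tests)
    _write(tests_df, out / "tests.tsv", written)

    animal_rows = groups[groups != "standard"].index
    support = quant.cluster_support(
        means.loc[animal_rows],
        B=config.bootstrap_B,
        seed=stage_seed(seeds["quant"], "bootstrap"),
    )
    dendro = {
        "labels": support.labels,
        "merges": support.linkage.tolist(),
        "nodes": [sorted(map(int, node)) for node in support.nodes],
        "bp": support.bp.tolist(),
        "au": support.au.tolist(),
        "flags": support.flags,
        "B": support.B,
    }
    with open(out / "dendrogram.json", "w") as fh:
        json.dump(dendro, fh, indent=1, sort_keys=True)
    written.append("dendrogram.json")

    pca_res = quant.pca(ma.M.T)
    pca_df = pca_res.scores.copy()
    pca_df.insert(0, "sample_id", pca_df.index)
    pca_df["stage"] = [
        next(s.stage for s in samples if s.sample_id == sid)
        for sid in pca_res.scores.index
    ]
    _write(pca_df, out / "pca.tsv", written)

    kd_wt_split = _kd_wt_split_support(support, groups)
    sig = tests_df[(tests_df["groupA"] == "preleukemic")]
    return {
        "n_amplicons": len(amplicons),
        "mann_whitney_sig_preleukemic": int((sig["p"] < 0.05).sum()),
        "mann_whitney_total_preleukemic": int(len(sig)),
        "pca_variance_ratio": pca_res.explained_variance_ratio[:3].tolist(),
        "kd_wt_split": kd_wt_split,
    }


def _kd_wt_split_support(support: quant.ClusterSupport, groups: pd.Series) -> dict:
    """Support of the node that best separates knockdown from wildtype samples."""
    wt = {i for i, lab in enumerate(support.labels) if groups[lab] == "wildtype"}
    best, best_score = None, -1.0
    for i, node in enumerate(support.nodes):
        inter = len(node & wt)
        jac = inter / len(node | wt)
        if jac > best_score:
            best_score, best = jac, i
    if best is None:
        return {}
    return {
        "jaccard_vs_wildtype": best_score,
        "bp": float(support.bp[best]),
        "au": float(support.au[best]),
    }
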