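"""Self-contained synthetic reference and experiment generator.

Emulates the statistical structure the analysis assumes: a small genome with
non-overlapping CpG islands tiled by 45-60 bp probes (plus off-island negative
controls), gene models anchored at island midpoints, transcription-factor
binding peaks placed with configurable odds toward a designated island subset,
and per-animal two-channel array intensities with normal background,
methylation-dependent specific signal and a smooth intensity-dependent dye
bias. Ground truth (which probes were planted hyper-/hypomethylated in which
disease stage, and every generative parameter) is retained so downstream
statistics can be scored against it.

The array signal model: each channel observes

    X = N(mu, sigma^2) + Gamma(k, mean = alpha * g(beta)),

where g(beta) = g0 + (g1 - g0) * beta is the linear enrichment response of the
methyl-CpG immunoprecipitation to the methylation fraction beta, and the Gamma
shape k models replicate-feature averaging (k = 1 reduces to the exponential
signal assumed by the NormExp background model; the default k keeps the
per-probe log-ratio noise at a level where a seven-animal stage has power).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .regions import GenomicInterval, merge_intervals, write_bed
from .annotation import ProbeRecord
from .sam import STAGES, classify_stage

__all__ = [
    "ConfigError",
    "DesignError",
    "SimConfig",
    "GeneModel",
    "Animal",
    "StageDesign",
    "SyntheticTruth",
    "SyntheticReference",
    "TwoColorSample",
    "default_design",
    "simulate_reference",
    "simulate_cohort",
    "simulate_massarray",
    "write_reference",
    "cohort_frame",
]


class ConfigError(ValueError):
    """Inconsistent simulation configuration."""


class DesignError(ValueError):
    """Invalid cohort design (unknown stage label, broken pairing)."""


@dataclass(frozen=True)
class GeneModel:
    """A gene with its TSS at the strand-appropriate end of its span."""

    gene_id: str
    chrom: str
    tss: int
    strand: str
    span: GenomicInterval

    def __post_init__(self) -> None:
        if self.strand == "+" and self.tss != self.span.start:
            raise ValueError("plus-strand TSS must sit at span start")
        if self.strand == "-" and self.tss != self.span.end - 1:
            raise ValueError("minus-strand TSS must sit at span end")


@dataclass(frozen=True)
class Animal:
    """One knockdown animal with its matched wildtype co-hybridisation partner."""

    animal_id: str
    blast_pct: float | None
    matched_wt: str
    stage: str | None = None  # explicit label overrides blast classification

    def resolve_stage(self) -> str:
        if self.stage is not None:
            if self.stage not in STAGES:
                raise DesignError(f"unknown stage label {self.stage!r}")
            return self.stage
        return classify_stage(self.blast_pct)


@dataclass
class StageDesign:
    """The cohort: one entry per knockdown animal, each paired 1:1 to a wildtype."""

    animals: list[Animal]

    def __post_init__(self) -> None:
        wt = [a.matched_wt for a in self.animals]
        if len(set(wt)) != len(wt):
            raise DesignError("matched-wildtype pairing must be one-to-one")
        for a in self.animals:
            a.resolve_stage()  # raises on bad labels / blast counts

    def stages(self) -> dict[str, str]:
        return {a.animal_id: a.resolve_stage() for a in self.animals}


@dataclass
class SimConfig:
    """Sizes, counts and generative parameters of the synthetic study."""

    n_chrom: int = 2
    chrom_len: int = 600_000
    n_cgi: int = 300
    cgi_len_range: tuple[int, int] = (600, 1400)
    n_probes: int = 1800          # total, negative controls included
    n_negctrl: int = 150
    probe_len_range: tuple[int, int] = (45, 60)
    gene_fraction: float = 0.7
    gene_len_range: tuple[int, int] = (4_000, 20_000)
    n_peaks: int = 200
    peak_len_range: tuple[int, int] = (150, 350)
    peak_rho: float = 10.0
    motif: str = "GAGGAA"
    motif_cgi_fraction: float = 0.5
    # planted differential methylation, in CpG islands per stage
    n_hyper_cgis: dict = field(
        default_factory=lambda: {
            "preleukemic": 30, "early_leukemic": 28, "late_leukemic": 100
        }
    )
    n_hypo_cgis: dict = field(
        default_factory=lambda: {
            "preleukemic": 15, "early_leukemic": 12, "late_leukemic": 15
        }
    )
    delta_beta: float = 0.45      # methylation gain at planted hyper islands
    delta_beta_hypo: float = 0.40
    beta_jitter: float = 0.02     # per-animal biological variation of beta
    # channel intensity model
    bg_mu: float = 50.0
    bg_sigma: float = 10.0
    alpha: float = 200.0          # mean specific signal at g(beta) = 1
    g0: float = 1.0
    g1: float = 6.0
    signal_shape: float = 30.0    # Gamma shape (replicate averaging); 1 = exponential
    dye_bias_amp: float = 0.5     # amplitude b of the M-offset b*sin(A/2)
    seed: int = 0

    def validate(self) -> None:
        if self.n_probes - self.n_negctrl < self.n_cgi:
            raise ConfigError("requested probe count must be >= CGI count")
        if self.chrom_len < 10_000:
            raise ConfigError("chromosome length must be >= 10 kb")
        per_chrom = -(-self.n_cgi // self.n_chrom)
        need = per_chrom * (self.cgi_len_range[1] + 2)
        if need > self.chrom_len:
            raise ConfigError("more CGIs than fit the genome")
        if self.peak_len_range[1] > self.cgi_len_range[0]:
            raise ConfigError("peaks must fit inside the smallest CGI")
        if sum(self.n_hyper_cgis.values()) + sum(self.n_hypo_cgis.values()) > self.n_cgi:
            raise ConfigError("planted island sets exceed the CGI count")
        if not 0 < self.delta_beta <= 1 or not 0 < self.delta_beta_hypo <= 1:
            raise ConfigError("delta beta must be in (0, 1]")
        if self.peak_rho < 1:
            raise ConfigError("peak enrichment odds rho must be >= 1")


@dataclass
class SyntheticTruth:
    """Ground truth of the generator, for scoring downstream inference."""

    planted_hyper: dict[str, list[str]]   # stage -> probe ids
    planted_hypo: dict[str, list[str]]
    hyper_cgis: dict[str, list[str]]      # stage -> CGI names
    hypo_cgis: dict[str, list[str]]
    designated_cgis: list[str]            # peak-enriched island subset
    motif_cgis: list[str]
    beta0: dict[str, float]               # probe id -> baseline methylation
    cgi_beta0: dict[str, float]
    delta_beta: float
    delta_beta_hypo: float
    peak_rho: float
    dye_bias_amp: float
    bg_mu: float
    bg_sigma: float
    alpha: float
    g0: float
    g1: float
    signal_shape: float


@dataclass
class SyntheticReference:
    """The synthetic array design: genome, islands, genes, probes, peaks, truth."""

    genome: dict[str, str]
    chrom_sizes: dict[str, int]
    cgis: list[GenomicInterval]
    genes: list[GeneModel]
    probes: list[ProbeRecord]
    peaks: list[GenomicInterval]
    truth: SyntheticTruth
    config: SimConfig

    @property
    def probe_ids(self) -> list[str]:
        return [p.probe_id for p in self.probes]

    @property
    def negctrl_mask(self) -> np.ndarray:
        return np.array([p.is_negative_control for p in self.probes])

    def cgi_by_name(self) -> dict[str, GenomicInterval]:
        return {c.name: c for c in self.cgis}


@dataclass
class TwoColorSample:
    """Raw two-channel intensities for one knockdown/wildtype co-hybridisation."""

    sample_id: str
    stage: str
    matched_wt: str
    R: np.ndarray  # knockdown channel
    G: np.ndarray  # wildtype channel
    blast_pct: float | None = None


def default_design() -> StageDesign:
    """The default cohort: 7 preleukemic, 5 early and 7 late leukemic animals.

    Two late-stage animals carry no blast count (they died before sampling in
    the modelled study) and are assigned the late label phenotypically.
    """
    animals = []
    blasts = {
        "preleukemic": [5, 8, 10, 12, 14, 16, 18],
        "early_leukemic": [20, 27, 35, 42, 50],
        "late_leukemic": [55, 65, 75, 85, 95],
    }
    i = 0
    for stage in STAGES:
        for b in blasts[stage]:
            i += 1
            animals.append(Animal(f"kd{i:02d}", float(b), f"wt{i:02d}"))
    for _ in range(2):  # blast count unavailable; label forced late leukemic
        i += 1
        animals.append(Animal(f"kd{i:02d}", None, f"wt{i:02d}", stage="late_leukemic"))
    return StageDesign(animals)


BASES = np.array(list("ACGT"))


def _place_cgis(cfg: SimConfig, rng: np.random.Generator) -> list[GenomicInterval]:
    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chrom)]
    base, rem = divmod(cfg.n_cgi, cfg.n_chrom)
    counts = [base + (1 if i < rem else 0) for i in range(cfg.n_chrom)]
    cgis = []
    k = 0
    lo, hi = cfg.cgi_len_range
    for chrom, n_c in zip(chrom_names, counts):
        lens = rng.integers(lo, hi + 1, size=n_c)
        total_gap = cfg.chrom_len - int(lens.sum())
        if total_gap < n_c + 1:
            raise ConfigError("more CGIs than fit the genome")
        w = rng.random(n_c + 1)
        gaps = np.floor(w / w.sum() * (total_gap - n_c - 1)).astype(int) + 1
        pos = 0
        for j in range(n_c):
            pos += int(gaps[j])
            k += 1
            cgis.append(GenomicInterval(chrom, pos, pos + int(lens[j]), f"cgi{k:04d}"))
            pos += int(lens[j])
    return cgis


def _plant_stage_sets(
    cfg: SimConfig, rng: np.random.Generator, cgi_names: list[str]
) -> tuple[dict[str, list[str]], dict[str, list[str]]]:
    """Overlapping per-stage planted island sets emulating disease progression.

    A common core is hypermethylated throughout; the late stage adds a large
    block of new islands, and each stage keeps a few unique ones. Hypomethylated
    sets are drawn from a disjoint pool.
    """
    idx = list(rng.permutation(len(cgi_names)))
    nh = cfg.n_hyper_cgis
    n_pre, n_early, n_late = (
        nh.get("preleukemic", 0), nh.get("early_leukemic", 0), nh.get("late_leukemic", 0)
    )
    core = max(1, min(n_pre, n_early, n_late) * 2 // 3)
    pre = idx[:n_pre]
    early = idx[:core] + idx[n_pre : n_pre + (n_early - core)]
    used = n_pre + (n_early - core)
    late = idx[:core] + idx[used : used + (n_late - core)]
    used += n_late - core
    pool = idx[used:]
    nl = cfg.n_hypo_cgis
    l_pre, l_early, l_late = (
        nl.get("preleukemic", 0), nl.get("early_leukemic", 0), nl.get("late_leukemic", 0)
    )
    lcore = max(1, min(l_pre, l_early, l_late) * 2 // 3)
    lpre = pool[:l_pre]
    learly = pool[:lcore] + pool[l_pre : l_pre + (l_early - lcore)]
    lused = l_pre + (l_early - lcore)
    llate = pool[:lcore] + pool[lused : lused + (l_late - lcore)]
    if lused + (l_late - lcore) > len(pool):
        raise ConfigError("planted island sets exceed the CGI count")
    hyper = {
        "preleukemic": sorted(cgi_names[i] for i in pre),
        "early_leukemic": sorted(cgi_names[i] for i in early),
        "late_leukemic": sorted(cgi_names[i] for i in late),
    }
    hypo = {
        "preleukemic": sorted(cgi_names[i] for i in lpre),
        "early_leukemic": sorted(cgi_names[i] for i in learly),
        "late_leukemic": sorted(cgi_names[i] for i in llate),
    }
    return hyper, hypo


def simulate_reference(config: SimConfig, seed: int | None = None) -> SyntheticReference:
    """Generate the full synthetic reference; deterministic for a fixed seed."""
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chrom)]
    chrom_sizes = {c: cfg.chrom_len for c in chrom_names}
    genome_arr = {
        c: rng.integers(0, 4, size=cfg.chrom_len) for c in chrom_names
    }

    cgis = _place_cgis(cfg, rng)
    cgi_names = [c.name for c in cgis]

    # plant exact motif occurrences in a configured fraction of islands
    n_motif = int(round(cfg.motif_cgi_fraction * len(cgis)))
    motif_idx = sorted(rng.choice(len(cgis), size=n_motif, replace=False))
    motif_codes = np.array(["ACGT".index(b) for b in cfg.motif.upper()])
    for i in motif_idx:
        cgi = cgis[i]
        pos = int(rng.integers(cgi.start, cgi.end - len(cfg.motif) + 1))
        genome_arr[cgi.chrom][pos : pos + len(motif_codes)] = motif_codes
    genome = {c: "".join(BASES[genome_arr[c]]) for c in chrom_names}

    # genes anchored near island midpoints
    genes: list[GeneModel] = []
    n_genes = int(round(cfg.gene_fraction * len(cgis)))
    gene_idx = sorted(rng.choice(len(cgis), size=n_genes, replace=False))
    for j, i in enumerate(gene_idx, start=1):
        cgi = cgis[i]
        tss = int((cgi.start + cgi.end) // 2 + rng.integers(-200, 201))
        strand = "+" if rng.random() < 0.5 else "-"
        length = int(rng.integers(*cfg.gene_len_range))
        if strand == "+":
            tss = min(tss, cfg.chrom_len - 2)
            span = GenomicInterval(cgi.chrom, tss, min(tss + length, cfg.chrom_len))
        else:
            tss = max(tss, 1)
            span = GenomicInterval(cgi.chrom, max(0, tss - length + 1), tss + 1)
        genes.append(GeneModel(f"gene{j:04d}", cgi.chrom, tss, strand, span))

    # probes tile the islands; negative controls live strictly off-island
    n_signal = cfg.n_probes - cfg.n_negctrl
    base, rem = divmod(n_signal, cfg.n_cgi)
    extra = set(map(int, rng.choice(cfg.n_cgi, size=rem, replace=False)))
    probes: list[ProbeRecord] = []
    pid = 0
    plo, phi = cfg.probe_len_range
    for i, cgi in enumerate(cgis):
        k = base + (1 if i in extra else 0)
        for j in range(k):
            pid += 1
            plen = int(rng.integers(plo, phi + 1))
            anchor = cgi.start + int((j + 0.5) * cgi.length / k) - plen // 2
            start = int(np.clip(anchor, cgi.start, cgi.end - plen))
            probes.append(
                ProbeRecord(
                    f"p{pid:06d}",
                    GenomicInterval(cgi.chrom, start, start + plen, f"p{pid:06d}"),
                    cgi_id=cgi.name,
                )
            )
    merged_cgis = merge_intervals(cgis)
    lens = np.array([chrom_sizes[c] for c in chrom_names], dtype=float)
    for _ in range(cfg.n_negctrl):
        while True:
            chrom = chrom_names[int(rng.choice(cfg.n_chrom, p=lens / lens.sum()))]
            plen = int(rng.integers(plo, phi + 1))
            start = int(rng.integers(0, cfg.chrom_len - plen + 1))
            t_starts, t_ends = merged_cgis.get(chrom, (np.array([]), np.array([])))
            pos = np.searchsorted(t_starts, start + plen, side="left")
            if pos > 0 and t_ends[pos - 1] > start:
                continue
            pid += 1
            probes.append(
                ProbeRecord(
                    f"p{pid:06d}",
                    GenomicInterval(chrom, start, start + plen, f"p{pid:06d}"),
                    is_negative_control=True,
                )
            )
            break

    hyper_cgis, hypo_cgis = _plant_stage_sets(cfg, rng, cgi_names)
    designated = hyper_cgis["preleukemic"]

    # baseline methylation per island: hypo islands start methylated, others low
    hypo_all = set().union(*hypo_cgis.values())
    cgi_beta0 = {}
    for c in cgis:
        if c.name in hypo_all:
            cgi_beta0[c.name] = float(rng.uniform(0.55, 0.75))
        else:
            cgi_beta0[c.name] = float(rng.uniform(0.05, 0.25))
    beta0 = {}
    for p in probes:
        if p.is_negative_control:
            beta0[p.probe_id] = float(rng.uniform(0.05, 0.25))
        else:
            beta0[p.probe_id] = cgi_beta0[p.cgi_id]

    # peaks: odds rho of landing inside the designated island subset
    by_name = {c.name: c for c in cgis}
    desig_ivs = [by_name[nm] for nm in designated]
    desig_len = sum(iv.length for iv in desig_ivs)
    w = desig_len / sum(chrom_sizes.values())
    p_in = cfg.peak_rho * w / (cfg.peak_rho * w + (1 - w))
    desig_weights = np.array([iv.length for iv in desig_ivs], dtype=float)
    desig_merged = merge_intervals(desig_ivs)
    peaks = []
    for j in range(1, cfg.n_peaks + 1):
        plen = int(rng.integers(*cfg.peak_len_range))
        if desig_ivs and rng.random() < p_in:
            iv = desig_ivs[int(rng.choice(len(desig_ivs), p=desig_weights / desig_weights.sum()))]
            start = int(rng.integers(iv.start, iv.end - plen + 1))
            chrom = iv.chrom
        else:
            while True:
                chrom = chrom_names[int(rng.choice(cfg.n_chrom, p=lens / lens.sum()))]
                start = int(rng.integers(0, cfg.chrom_len - plen + 1))
                t_starts, t_ends = desig_merged.get(chrom, (np.array([]), np.array([])))
                pos = np.searchsorted(t_starts, start + plen, side="left")
                if pos > 0 and len(t_ends) and t_ends[pos - 1] > start:
                    continue
                break
        peaks.append(GenomicInterval(chrom, start, start + plen, f"peak{j:04d}"))

    probe_by_cgi: dict[str, list[str]] = {}
    for p in probes:
        if p.cgi_id:
            probe_by_cgi.setdefault(p.cgi_id, []).append(p.probe_id)
    planted_hyper = {
        st: sorted(pid for nm in hyper_cgis[st] for pid in probe_by_cgi.get(nm, []))
        for st in STAGES
    }
    planted_hypo = {
        st: sorted(pid for nm in hypo_cgis[st] for pid in probe_by_cgi.get(nm, []))
        for st in STAGES
    }

    truth = SyntheticTruth(
        planted_hyper=planted_hyper,
        planted_hypo=planted_hypo,
        hyper_cgis=hyper_cgis,
        hypo_cgis=hypo_cgis,
        designated_cgis=list(designated),
        motif_cgis=sorted(cgi_names[i] for i in motif_idx),
        beta0=beta0,
        cgi_beta0=cgi_beta0,
        delta_beta=cfg.delta_beta,
        delta_beta_hypo=cfg.delta_beta_hypo,
        peak_rho=cfg.peak_rho,
        dye_bias_amp=cfg.dye_bias_amp,
        bg_mu=cfg.bg_mu,
        bg_sigma=cfg.bg_sigma,
        alpha=cfg.alpha,
        g0=cfg.g0,
        g1=cfg.g1,
        signal_shape=cfg.signal_shape,
    )
    return SyntheticReference(
        genome=genome,
        chrom_sizes=chrom_sizes,
        cgis=cgis,
        genes=genes,
        probes=probes,
        peaks=peaks,
        truth=truth,
        config=cfg,
    )


def _g(beta: np.ndarray, cfg: SimConfig) -> np.ndarray:
    return cfg.g0 + (cfg.g1 - cfg.g0) * beta


def _channel(
    beta: np.ndarray, cfg: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    bg = rng.normal(cfg.bg_mu, cfg.bg_sigma, size=beta.size)
    mean_sig = cfg.alpha * _g(beta, cfg)
    sig = rng.gamma(cfg.signal_shape, mean_sig / cfg.signal_shape)
    return np.maximum(bg + sig, 0.5)


def simulate_cohort(
    ref: SyntheticReference, design: StageDesign, seed: int = 0
) -> list[TwoColorSample]:
    """Two-channel intensities for every knockdown/wildtype pair in the design."""
    cfg = ref.config
    rng = np.random.default_rng(seed)
    probe_ids = ref.probe_ids
    beta0 = np.array([ref.truth.beta0[p] for p in probe_ids])
    idx = {p: i for i, p in enumerate(probe_ids)}
    samples = []
    for animal in design.animals:
        stage = animal.resolve_stage()
        hyper = np.zeros(len(probe_ids), dtype=bool)
        hypo = np.zeros(len(probe_ids), dtype=bool)
        for p in ref.truth.planted_hyper[stage]:
            hyper[idx[p]] = True
        for p in ref.truth.planted_hypo[stage]:
            hypo[idx[p]] = True
        beta_wt = np.clip(beta0 + rng.normal(0, cfg.beta_jitter, beta0.size), 0.01, 0.99)
        beta_kd = np.clip(
            beta0
            + rng.normal(0, cfg.beta_jitter, beta0.size)
            + cfg.delta_beta * hyper
            - cfg.delta_beta_hypo * hypo,
            0.01,
            0.99,
        )
        g_ch = _channel(beta_wt, cfg, rng)
        r_ch = _channel(beta_kd, cfg, rng)
        if cfg.dye_bias_amp:
            a0 = 0.5 * (np.log2(r_ch) + np.log2(g_ch))
            r_ch = r_ch * 2.0 ** (cfg.dye_bias_amp * np.sin(a0 / 2.0))
        samples.append(
            TwoColorSample(
                sample_id=animal.animal_id,
                stage=stage,
                matched_wt=animal.matched_wt,
                R=r_ch,
                G=g_ch,
                blast_pct=animal.blast_pct,
            )
        )
    return samples


def simulate_massarray(
    ref: SyntheticReference,
    design: StageDesign,
    amplicons: Sequence[tuple[str, str]],
    seed: int = 0,
    n_units: int = 8,
    noise_sd: float = 0.05,
    missing_rate: float = 0.05,
):
    """Noisy amplicon CpG-unit methylation fractions with standard-curve rows.

    ``amplicons`` maps amplicon ids to CGI names; each amplicon gets
    ``n_units`` CpG-unit columns. Every knockdown animal, each distinct
    matched wildtype, and six standards mixed at 0/20/40/60/80/100%
    methylation appear as rows; values are clip(beta + noise, 0, 1) and
    missingness is injected at ``missing_rate`` into animal rows only.
    """
    from .quant import AmpliconTable

    cfg = ref.config
    known = {c.name for c in ref.cgis}
    for amp, cgi in amplicons:
        if cgi not in known:
            raise ValueError(f"amplicon {amp!r} maps to no CGI ({cgi!r})")
    rng = np.random.default_rng(seed)
    units, unit_amp = [], {}
    for amp, _ in amplicons:
        for u in range(1, n_units + 1):
            col = f"{amp}.cg{u}"
            units.append(col)
            unit_amp[col] = amp

    rows, groups = [], {}
    index = []

    def add_row(sample_id: str, group: str, betas: np.ndarray, missing: bool) -> None:
        vals = np.clip(betas + rng.normal(0, noise_sd, betas.size), 0.0, 1.0)
        if missing and missing_rate > 0:
            mask = rng.random(betas.size) < missing_rate
            vals[mask] = np.nan
        rows.append(vals)
        groups[sample_id] = group
        index.append(sample_id)

    hyper = ref.truth.hyper_cgis
    hypo = ref.truth.hypo_cgis
    for animal in design.animals:
        stage = animal.resolve_stage()
        betas = []
        for amp, cgi in amplicons:
            b = ref.truth.cgi_beta0[cgi]
            if cgi in hyper[stage]:
                b = min(b + cfg.delta_beta, 1.0)
            if cgi in hypo[stage]:
                b = max(b - cfg.delta_beta_hypo, 0.0)
            betas.extend([b] * n_units)
        add_row(animal.animal_id, stage, np.array(betas), missing=True)
    for animal in design.animals:
        betas = []
        for amp, cgi in amplicons:
            betas.extend([ref.truth.cgi_beta0[cgi]] * n_units)
        add_row(animal.matched_wt, "wildtype", np.array(betas), missing=True)
    for level in (0.0, 0.2, 0.4, 0.6, 0.8, 1.0):
        add_row(
            f"std{int(level * 100):03d}",
            "standard",
            np.full(len(units), level),
            missing=False,
        )

    values = pd.DataFrame(rows, index=index, columns=units)
    return AmpliconTable(
        values=values,
        unit_amplicon=pd.Series(unit_amp),
        sample_group=pd.Series(groups),
    )


def cohort_frame(ref: SyntheticReference, samples: Sequence[TwoColorSample]) -> pd.DataFrame:
    """Long-format intensity table (probe_id, sample_id, channel_R, channel_G)."""
    frames = []
    for s in samples:
        frames.append(
            pd.DataFrame(
                {
                    "probe_id": ref.probe_ids,
                    "sample_id": s.sample_id,
                    "channel_R": s.R,
                    "channel_G": s.G,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_reference(ref: SyntheticReference, outdir: str | Path) -> None:
    """Write FASTA/BED/TSV/JSON artifacts of the reference to a directory."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    records = [
        SeqRecord(Seq(ref.genome[c]), id=c, description="") for c in ref.genome
    ]
    SeqIO.write(records, str(out / "genome.fa"), "fasta")
    write_bed(ref.cgis, out / "cgis.bed")
    write_bed([p.interval for p in ref.probes], out / "probes.bed")
    write_bed(ref.peaks, out / "peaks.bed")
    pd.DataFrame(
        [
            {
                "probe_id": p.probe_id,
                "chrom": p.interval.chrom,
                "start": p.interval.start,
                "end": p.interval.end,
                "cgi_id": p.cgi_id or "",
                "is_negative_control": int(p.is_negative_control),
            }
            for p in ref.probes
        ]
    ).to_csv(out / "probes.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "gene_id": g.gene_id,
                "chrom": g.chrom,
                "tss": g.tss,
                "strand": g.strand,
                "start": g.span.start,
                "end": g.span.end,
            }
            for g in ref.genes
        ]
    ).to_csv(out / "genes.tsv", sep="\t", index=False)
    with open(out / "chrom_sizes.tsv", "w") as fh:
        for c, size in ref.chrom_sizes.items():
            fh.write(f"{c}\t{size}\n")
    with open(out / "truth.json", "w") as fh:
        json.dump(asdict(ref.truth), fh, indent=1, sort_keys=True)
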