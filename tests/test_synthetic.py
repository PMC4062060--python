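"""Synthetic reference/cohort generator: geometry, determinism, ground truth."""
import numpy as np
import pytest

from methprog.enrichment import scan_motif
from methprog.regions import overlap_indicator
from methprog.synthetic import (
    Animal,
    ConfigError,
    DesignError,
    SimConfig,
    StageDesign,
    default_design,
    simulate_cohort,
    simulate_massarray,
    simulate_reference,
    write_reference,
)


class TestSimulateReference:
    def test_counts_are_config_forced(self):
        cfg = SimConfig(n_chrom=2, chrom_len=500_000, n_cgi=200, n_probes=1000,
                        n_negctrl=100, n_peaks=50)
        r = simulate_reference(cfg, seed=7)
        assert len(r.probes) == 1000
        assert len(r.cgis) == 200
        assert sum(p.is_negative_control for p in r.probes) == 100
        assert len(r.peaks) == 50

    def test_probe_geometry_invariants(self, ref):
        for p in ref.probes:
            assert 45 <= p.interval.length <= 60
            assert p.interval.end <= ref.chrom_sizes[p.interval.chrom]
        neg = [p.interval for p in ref.probes if p.is_negative_control]
        assert overlap_indicator(neg, ref.cgis).sum() == 0

    def test_cgis_sorted_and_non_overlapping(self, ref):
        last_end = {}
        for c in ref.cgis:
            assert c.start >= last_end.get(c.chrom, 0)
            last_end[c.chrom] = c.end

    def test_planted_motifs_present_in_designated_islands(self, ref):
        sites = scan_motif(ref.genome, ref.config.motif)
        motif_cgis = [c for c in ref.cgis if c.name in set(ref.truth.motif_cgis)]
        hit = overlap_indicator(motif_cgis, sites)
        assert hit.all()  # every designated island carries >= 1 exact occurrence
        assert len(motif_cgis) == round(ref.config.motif_cgi_fraction * len(ref.cgis))

    def test_same_seed_gives_byte_identical_outputs(self, tmp_path):
        cfg = SimConfig(n_cgi=60, n_probes=400, n_negctrl=40, n_peaks=30,
                        n_hyper_cgis={"preleukemic": 6, "early_leukemic": 6, "late_leukemic": 15},
                        n_hypo_cgis={"preleukemic": 4, "early_leukemic": 3, "late_leukemic": 4})
        for d in ("a", "b"):
            write_reference(simulate_reference(cfg, seed=13), tmp_path / d)
        for name in ("genome.fa", "cgis.bed", "probes.bed", "peaks.bed",
                     "genes.tsv", "truth.json"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_rho_one_peak_placement_matches_subset_share(self):
        fracs, ws = [], []
        for seed in range(20):
            r = simulate_reference(SimConfig(peak_rho=1.0), seed=100 + seed)
            desig = [c for c in r.cgis if c.name in set(r.truth.designated_cgis)]
            fracs.append(overlap_indicator(r.peaks, desig).mean())
            ws.append(sum(c.length for c in desig) / sum(r.chrom_sizes.values()))
        n = 20 * len(r.peaks)
        w = float(np.mean(ws))
        se = np.sqrt(w * (1 - w) / n)
        assert abs(np.mean(fracs) - w) < 3 * se

    def test_planted_sets_disjoint_from_negative_controls(self, ref):
        neg = {p.probe_id for p in ref.probes if p.is_negative_control}
        for st in ref.truth.planted_hyper:
            assert not (set(ref.truth.planted_hyper[st]) & neg)
            assert not (set(ref.truth.planted_hypo[st]) & neg)

    def test_inconsistent_config_rejected(self):
        with pytest.raises(ConfigError):
            simulate_reference(SimConfig(n_cgi=500, n_probes=400), seed=0)
        with pytest.raises(ConfigError):
            simulate_reference(SimConfig(chrom_len=20_000, n_cgi=300), seed=0)
        with pytest.raises(ConfigError):
            simulate_reference(SimConfig(peak_rho=0.5), seed=0)


class TestSimulateCohort:
    def test_fixed_seed_identical_intensities(self, ref, design):
        a = simulate_cohort(ref, design, seed=3)
        b = simulate_cohort(ref, design, seed=3)
        for x, y in zip(a, b):
            assert np.array_equal(x.R, y.R) and np.array_equal(x.G, y.G)

    def test_intensities_strictly_positive(self, cohort):
        for s in cohort:
            assert (s.R > 0).all() and (s.G > 0).all()

    def test_no_effect_no_bias_gives_symmetric_null(self):
        cfg = SimConfig(dye_bias_amp=0.0)
        r = simulate_reference(cfg, seed=21)
        samples = simulate_cohort(r, default_design(), seed=22)
        s = samples[0]
        planted = set(r.truth.planted_hyper[s.stage]) | set(r.truth.planted_hypo[s.stage])
        null = np.array([pid not in planted for pid in r.probe_ids])
        m = np.log2(s.R / s.G)
        assert abs(m[null].mean()) < 0.05

    @pytest.mark.parametrize("seed", range(10))
    def test_planted_probes_have_higher_m_than_null(self, ref, design, seed):
        samples = simulate_cohort(ref, design, seed=seed)
        s = samples[0]  # a preleukemic animal
        hyper = set(ref.truth.planted_hyper[s.stage])
        hypo = set(ref.truth.planted_hypo[s.stage])
        m = np.log2(s.R / s.G)
        is_hyper = np.array([pid in hyper for pid in ref.probe_ids])
        null = np.array([pid not in hyper and pid not in hypo for pid in ref.probe_ids])
        assert m[is_hyper].mean() > m[null].mean() + 0.5

    def test_background_subtracted_mean_matches_alpha(self):
        # flat enrichment response isolates the exponential-signal mean
        cfg = SimConfig(g0=1.0, g1=1.0, dye_bias_amp=0.0, n_probes=5000,
                        n_negctrl=200, n_cgi=300)
        r = simulate_reference(cfg, seed=31)
        s = simulate_cohort(r, default_design(), seed=32)[0]
        for channel in (s.R, s.G):
            signal = channel.mean() - cfg.bg_mu
            se = channel.std() / np.sqrt(channel.size)
            assert abs(signal - cfg.alpha) < 3 * se

    def test_unknown_stage_label_rejected(self, ref):
        with pytest.raises(DesignError):
            StageDesign([Animal("kd1", None, "wt1", stage="chronic")])

    def test_duplicate_wildtype_pairing_rejected(self):
        with pytest.raises(DesignError):
            StageDesign([Animal("kd1", 10, "wt1"), Animal("kd2", 12, "wt1")])


class TestSimulateMassarray:
    def amplicons(self, ref, n=4):
        planted = ref.truth.hyper_cgis["preleukemic"][:n // 2]
        others = [c.name for c in ref.cgis
                  if c.name not in set().union(*ref.truth.hyper_cgis.values())
                  and c.name not in set().union(*ref.truth.hypo_cgis.values())]
        names = planted + others[: n - len(planted)]
        return [(f"amp{i}", nm) for i, nm in enumerate(names)]

    def test_noise_free_standards_read_exact_levels(self, ref, design):
        t = simulate_massarray(ref, design, self.amplicons(ref), seed=1,
                               noise_sd=0.0, missing_rate=0.0)
        stds = t.sample_group[t.sample_group == "standard"].index
        vals = t.values.loc[stds]
        expected = np.array([0.0, 0.2, 0.4, 0.6, 0.8, 1.0])
        assert np.allclose(np.sort(vals.mean(axis=1).values), expected)
        assert (vals.nunique(axis=1) == 1).all()  # constant across units

    def test_zero_missing_rate_has_no_missing_cells(self, ref, design):
        t = simulate_massarray(ref, design, self.amplicons(ref), seed=2,
                               missing_rate=0.0)
        assert not t.values.isna().any().any()

    @pytest.mark.parametrize("seed", range(10))
    def test_planted_amplicons_higher_in_kd_than_wt(self, ref, design, seed):
        amps = self.amplicons(ref)
        t = simulate_massarray(ref, design, amps, seed=seed)
        planted_units = [u for u in t.values.columns
                         if t.unit_amplicon[u] in ("amp0", "amp1")]
        pre = t.sample_group[t.sample_group == "preleukemic"].index
        wt = t.sample_group[t.sample_group == "wildtype"].index
        kd_mean = t.values.loc[pre, planted_units].mean().mean()
        wt_mean = t.values.loc[wt, planted_units].mean().mean()
        assert kd_mean > wt_mean

    def test_amplicon_outside_any_island_rejected(self, ref, design):
        with pytest.raises(ValueError):
            simulate_massarray(ref, design, [("ampX", "no-such-cgi")], seed=0)


def test_default_design_matches_study_structure():
    d = default_design()
    stages = [a.resolve_stage() for a in d.animals]
    assert stages.count("preleukemic") == 7
    assert stages.count("early_leukemic") == 5
    assert stages.count("late_leukemic") == 7
    forced = [a for a in d.animals if a.blast_pct is None]
    assert len(forced) == 2  # phenotypically assigned late-stage animals
    assert all(a.stage == "late_leukemic" for a in forced)
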