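import numpy as np
import pytest

from flexlink import relaxation as rx
from flexlink.datatypes import BeadModel
from flexlink.ensemble import generate_conformers
from flexlink.synthetic import (
    SyntheticTruth,
    default_two_domain_dynamics,
    make_two_domain_model,
    simulate_relaxation,
    simulate_saxs,
    simulate_titration,
)


class TestTwoDomainModel:
    def test_bead_counts(self):
        assert len(make_two_domain_model(15, 20, 60, seed=0)) == 95
        assert len(make_two_domain_model(0, 20, 60, seed=0)) == 80

    def test_domain_labels_and_flexible_set(self, topology):
        labels = list(topology.domains)
        assert labels[:15] == ["UIM"] * 15
        assert labels[15:35] == ["linker"] * 20
        assert labels[35:] == ["SH3"] * 60
        assert topology.flexible == frozenset(range(16, 36))

    def test_geometry_invariants_over_seeds(self):
        for seed in range(4):
            m = make_two_domain_model(15, 20, 60, seed=seed)  # validates on construction
            assert isinstance(m, BeadModel)

    def test_helix_deletion_gives_more_compact_pool(self):
        full_pool = generate_conformers(make_two_domain_model(15, 20, 60, seed=0), 20, seed=3)
        short_pool = generate_conformers(make_two_domain_model(0, 20, 60, seed=0), 20, seed=3)
        assert short_pool.rgs.mean() < full_pool.rgs.mean()

    def test_shorter_linker_reduces_max_rg(self):
        long_pool = generate_conformers(make_two_domain_model(15, 20, 60, seed=0), 25, seed=4)
        short_pool = generate_conformers(make_two_domain_model(15, 13, 60, seed=0), 25, seed=4)
        assert short_pool.rgs.max() < long_pool.rgs.max()

    def test_bad_lengths_rejected(self):
        with pytest.raises(ValueError):
            make_two_domain_model(15, 0, 60)


class TestSimulateTitration:
    def test_bit_reproducible_and_truth_roundtrip(self, tmp_path):
        dd = {i: 0.7 for i in range(1, 6)}
        ladder = np.linspace(0, 500, 12)
        t1, truth = simulate_titration(86.0, dd, "1to1", 100.0, ladder, seed=11)
        t2, _ = simulate_titration(86.0, dd, "1to1", 100.0, ladder, seed=11)
        np.testing.assert_array_equal(t1.dH.values, t2.dH.values)
        truth.to_json(tmp_path / "truth.json")
        back = SyntheticTruth.from_json(tmp_path / "truth.json")
        assert back == truth
        # truth record regenerates the dataset bit-exactly
        t3, _ = simulate_titration(back.params["Kd"],
                                   {int(k): v for k, v in back.params["dd_bound"].items()},
                                   back.params["model"], back.params["P0"],
                                   back.params["L0"], back.params["noise"], back.seed)
        np.testing.assert_array_equal(t1.dN.values, t3.dN.values)

    def test_split_convention_inverts_exactly(self):
        from flexlink.titration import fit_kd, series_from_table

        dd = {i: 0.9 for i in range(1, 6)}
        table, _ = simulate_titration(120.0, dd, "1to1", 100.0, np.linspace(0, 500, 12),
                                      noise=0.0, seed=0, domains={i: "D" for i in dd})
        fit = fit_kd(series_from_table(table))
        assert fit.domain_kd["D"][0] == pytest.approx(120.0, abs=1e-4)

    def test_truncated_ladder_inflates_kd_sd(self):
        from flexlink.titration import fit_kd, series_from_table

        rng = np.random.default_rng(0)
        dd = {i: float(v) for i, v in enumerate(rng.uniform(0.4, 1.0, 20), start=1)}
        dom = {i: "D" for i in dd}
        full_sds, trunc_sds = [], []
        for seed in range(5):
            t_full, _ = simulate_titration(86.0, dd, "1to1", 100.0,
                                           np.linspace(0, 500, 12), 0.005, seed, dom)
            # ladder stopping near 20 % saturation of the 1:1 isotherm
            t_trunc, _ = simulate_titration(86.0, dd, "1to1", 100.0,
                                            np.linspace(0, 35, 12), 0.005, seed, dom)
            full_sds.append(fit_kd(series_from_table(t_full)).domain_kd["D"][1])
            trunc_sds.append(fit_kd(series_from_table(t_trunc)).domain_kd["D"][1])
        assert np.mean(trunc_sds) >= 3.0 * np.mean(full_sds)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            simulate_titration(86.0, {1: 0.5}, "1to1", 100.0, [0.0, 100.0], noise=-0.1)


class TestSimulateRelaxation:
    def test_rigid_limit_matches_lorentzian(self):
        tabs, _ = simulate_relaxation({"D": 8.0}, {1: 1.0}, {1: "D"}, tau_e_ps=0.0,
                                      noise=0.0, seed=0)
        recs = rx.records_from_tables(tabs["R1"], tabs["R2"], tabs["NOE_sat"], tabs["NOE_ref"])
        R1, R2, NOE = rx.rates_from_j(lambda w: rx.lorentzian_j(w, 8e-9),
                                      rx.PhysicalConstantsSet())
        assert recs[0].R1 == pytest.approx(R1, rel=1e-4)
        assert recs[0].R2 == pytest.approx(R2, rel=1e-4)
        assert recs[0].NOE == pytest.approx(NOE, rel=1e-6)

    def test_r2_gap_shrinks_with_stiffer_linker(self):
        S2, dom = default_two_domain_dynamics()

        def r2_gap(linker_s2):
            s2 = {r: (linker_s2 if d == "linker" else v) for (r, v), d in
                  zip(S2.items(), dom.values())}
            tabs, _ = simulate_relaxation({"UIM": 6.0, "linker": 7.0, "SH3": 9.0},
                                          s2, dom, noise=0.0, seed=0)
            recs = rx.records_from_tables(tabs["R1"], tabs["R2"], tabs["NOE_sat"],
                                          tabs["NOE_ref"], dom)
            r2 = {lab: np.mean([r.R2 for r in recs if r.domain == lab]) for lab in ("UIM", "SH3")}
            return r2["SH3"] - r2["UIM"]

        gap_floppy = r2_gap(0.3)
        gap_stiff = r2_gap(0.9)
        assert gap_floppy > 0
        # stiffer linker leaves the per-domain rates unchanged here (each
        # residue keeps its domain tau_c), so the gap must not grow
        assert gap_stiff <= gap_floppy + 1e-9

    def test_flexible_tail_negative_noe(self):
        tabs, _ = simulate_relaxation({"tail": 1.0}, {1: 0.2, 2: 0.2}, {1: "tail", 2: "tail"},
                                      tau_e_ps=1000.0, noise=0.0, seed=0)
        recs = rx.records_from_tables(tabs["R1"], tabs["R2"], tabs["NOE_sat"], tabs["NOE_ref"])
        assert recs[0].NOE < 0

    def test_unphysical_parameters_rejected(self):
        with pytest.raises(ValueError):
            simulate_relaxation({"D": 80.0}, {1: 0.9}, {1: "D"})
        with pytest.raises(ValueError):
            simulate_relaxation({"D": 8.0}, {1: 1.4}, {1: "D"})


class TestSimulateSAXS:
    def test_zero_noise_self_chi(self, pool):
        from flexlink.ensemble import chi_score

        prof, _ = simulate_saxs(pool, {3: 1.0}, noise_a=1e-9, seed=0)
        chi, c = chi_score(prof, pool.profiles[3])
        assert chi == pytest.approx(1.0, abs=0.5)  # residuals are ~1 sigma by construction
        assert c == pytest.approx(1.0, rel=1e-6)

    def test_noise_scale_degrades_weight_recovery(self, pool):
        from flexlink.ensemble import multistate_fit

        a, b = int(np.argmin(pool.rgs)), int(np.argmax(pool.rgs))
        errs = {}
        for scale in (0.01, 0.1):
            e = []
            for seed in range(8):
                prof, _ = simulate_saxs(pool, {a: 0.7, b: 0.3}, noise_a=scale, seed=seed)
                m = multistate_fit(pool, prof, 2, keep=1)[0]
                w = dict(zip(m.members, m.weights))
                e.append(abs(w.get(a, 0.0) - 0.7))
            errs[scale] = np.mean(e)
        assert errs[0.1] > errs[0.01]

    def test_weights_must_sum_to_one(self, pool):
        with pytest.raises(ValueError):
            simulate_saxs(pool, {0: 0.5, 1: 0.2})


def test_generators_roundtrip_through_files(tmp_path, topology):
    """Generated data written to disk pass the readers' validation."""
    from flexlink import io as fio

    dd = {i: 0.6 for i in range(1, 11)}
    table, _ = simulate_titration(86.0, dd, "1to1", 100.0, np.linspace(0, 500, 10), seed=1)
    fio.write_titration_table(table, tmp_path / "t.tsv")
    assert fio.read_titration_table(tmp_path / "t.tsv").n_points == 10

    tabs, _ = simulate_relaxation({"D": 8.0}, {1: 0.85, 2: 0.9}, {1: "D", 2: "D"}, seed=1)
    for name, t in tabs.items():
        fio.write_intensity_table(t, tmp_path / f"{name}.tsv")
        assert fio.read_intensity_table(tmp_path / f"{name}.tsv").experiment == name

    pool = generate_conformers(topology, 3, seed=5)
    prof, _ = simulate_saxs(pool, {0: 1.0}, seed=1)
    fio.write_saxs_dat(prof, tmp_path / "s.dat")
    assert len(fio.read_saxs_dat(tmp_path / "s.dat")) == len(prof)

    fio.write_coordinates(topology, tmp_path / "m.pdb")
    assert len(fio.read_coordinates(tmp_path / "m.pdb")) == len(topology)
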