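"""Synthetic-data generators: determinism, dimensions, planted truth."""

import numpy as np
import pytest

from mercikit import copynumber as cn
from mercikit.pipeline import run_merci, run_urcall
from mercikit.synth import (
    DEFAULT_STEP_FRACTIONS,
    ComplexSpec,
    GenomeSpec,
    simulate_copynumber,
    simulate_fractionation,
    simulate_titration,
)


class TestSimulateFractionation:
    def test_paper_shaped_dimensions(self):
        tables, refs, truth = simulate_fractionation(
            complexes=[ComplexSpec(("BAIT", "PARTNER"))], seed=0
        )
        assert sum(DEFAULT_STEP_FRACTIONS) == 83
        assert len(tables) == 5
        # 138 background + 2 members + 2 spike-ins
        assert all(len(t.proteins) == 142 for t in tables.values())
        t1 = tables[1]
        assert len(t1.fraction_runs()) == DEFAULT_STEP_FRACTIONS[0] * 3

    def test_seeded_rerun_identical(self):
        a, _, _ = simulate_fractionation(seed=42)
        b, _, _ = simulate_fractionation(seed=42)
        for step in a:
            assert a[step].areas.equals(b[step].areas)

    def test_different_seeds_differ(self):
        a, _, _ = simulate_fractionation(seed=1)
        b, _, _ = simulate_fractionation(seed=2)
        assert not a[1].areas.equals(b[1].areas)

    def test_noiseless_complex_members_correlate_exactly(self):
        tables, refs, _ = simulate_fractionation(
            n_background=20,
            complexes=[ComplexSpec(("BAIT", "PARTNER"))],
            noise_sd=0.0, seed=5,
        )
        ranked = run_merci(tables, refs, "BAIT")
        assert ranked.pcc("PARTNER") == pytest.approx(1.0, abs=1e-12)

    def test_detection_limit_censors_step(self):
        tables, _, truth = simulate_fractionation(
            n_background=30, detection_limit=5.0, seed=3
        )
        censored = {p for ps in truth.censored.values() for p in ps}
        assert censored  # lognormal amplitudes put some below 5
        for step, table in tables.items():
            for p in truth.censored[step]:
                assert p not in table.proteins

    def test_member_id_collision_rejected(self):
        with pytest.raises(ValueError, match="collide"):
            simulate_fractionation(
                n_background=3, complexes=[ComplexSpec(("BG000",))], seed=0
            )


class TestSimulateCopynumber:
    def _spec(self, **kw):
        defaults = dict(
            arm_lengths={"2L": 2_000_000},
            domains=[("2L", 800_000, 950_000, 0.51, {"mut": 86.0})],
            noise_sd=0.05,
        )
        defaults.update(kw)
        return GenomeSpec(**defaults)

    def test_full_recovery_restores_level(self):
        spec = self._spec(
            domains=[("2L", 800_000, 950_000, 0.5, {"mut": 100.0})],
            noise_sd=0.0,
        )
        tracks, _ = simulate_copynumber(spec, ["mut"], seed=0)
        mut = tracks["mut"][0].df
        inside = mut[(mut["start"] >= 800_000) & (mut["end"] <= 950_000)]
        outside = mut[(mut["end"] <= 800_000)]
        assert inside["value"].mean() == pytest.approx(
            outside["value"].mean()
        )

    def test_zero_recovery_equals_control(self):
        spec = self._spec(
            domains=[("2L", 800_000, 950_000, 0.5, {"mut": 0.0})],
            noise_sd=0.0,
        )
        tracks, _ = simulate_copynumber(spec, ["mut"], seed=0)
        # depth functions identical; only library-size factors differ
        ctrl = tracks["control"][0].df["value"].to_numpy()
        mut = tracks["mut"][0].df["value"].to_numpy()
        np.testing.assert_allclose(mut / mut[0], ctrl / ctrl[0], rtol=1e-12)

    def test_pipeline_round_trip_recovers_planted_truth(self):
        spec = self._spec()
        tracks, truth = simulate_copynumber(spec, ["mut"], seed=11)
        domains, _ = run_urcall(
            tracks["control"][0], tracks["diploid"][0],
            {"mut": tracks["mut"][0]},
        )
        assert len(domains) == 1
        d = domains[0]
        planted = truth["domains"][0]
        assert abs(d.start - planted["start"]) <= spec.bin_size
        assert abs(d.end - planted["end"]) <= spec.bin_size
        assert d.cn["control"] == pytest.approx(
            planted["control_depth"], abs=0.05
        )
        assert d.recovery_pct["mut"] == pytest.approx(
            planted["recovery_pct"]["mut"], abs=5.0
        )

    def test_overlapping_planted_domains_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            GenomeSpec(
                arm_lengths={"2L": 1_000_000},
                domains=[
                    ("2L", 100_000, 300_000, 0.5, {}),
                    ("2L", 250_000, 400_000, 0.5, {}),
                ],
            )

    def test_seeded_determinism(self):
        spec = self._spec()
        a, _ = simulate_copynumber(spec, ["mut"], seed=9)
        b, _ = simulate_copynumber(spec, ["mut"], seed=9)
        assert a["control"][0].df.equals(b["control"][0].df)


class TestSimulateTitration:
    def test_noiseless_exact_recovery(self):
        from mercikit.abundance import fit_titration

        pts, truth = simulate_titration(slope=1.1, intercept=-2.3,
                                        noise=0.0, seed=0)
        curve = fit_titration(pts)
        assert curve.slope == pytest.approx(truth["slope"], abs=1e-10)
        assert curve.intercept == pytest.approx(truth["intercept"],
                                                abs=1e-10)

    def test_seeded_determinism(self):
        a, _ = simulate_titration(noise=0.1, seed=4)
        b, _ = simulate_titration(noise=0.1, seed=4)
        assert a == b
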