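import numpy as np
import pytest

from caridelim.morphoscreen import (
    CandidateDiagnosis,
    CharacterMatrix,
    ScreeningTrace,
    block_validate,
    final_check,
    initial_screen,
    run_screen,
)
from caridelim.synthdata import CharacterSpec, MorphScenario, simulate_morphology

from conftest import make_character_matrix

CLADES = ("cladeA", "cladeB")


def voucher_rows(n_a, n_b, char, state_a="long", state_b="short", lot_a="A1", lot_b="B1"):
    rows = []
    for i in range(n_a):
        rows.append((f"a{i}", lot_a, "cladeA", "adult", True, {char: state_a}))
    for i in range(n_b):
        rows.append((f"b{i}", lot_b, "cladeB", "adult", True, {char: state_b}))
    return rows


class TestInitialScreen:
    def test_perfectly_diagnostic_character(self):
        m = make_character_matrix(voucher_rows(5, 5, "c1"), ["c1"])
        cands = initial_screen(m, CLADES)
        assert len(cands) == 1
        assert cands[0].constancy == {"cladeA": 1.0, "cladeB": 1.0}
        assert cands[0].modal_states == {"cladeA": "long", "cladeB": "short"}

    def test_exactly_080_fails_strict_threshold(self):
        rows = voucher_rows(5, 5, "c1")
        # make one cladeA specimen deviate: 4/5 = 0.8, not > 0.80
        rows[0] = ("a0", "A1", "cladeA", "adult", True, {"c1": "short"})
        m = make_character_matrix(rows, ["c1"])
        assert initial_screen(m, CLADES) == []

    def test_identical_modal_states_never_candidate(self):
        rows = voucher_rows(5, 5, "c1", state_a="long", state_b="long")
        m = make_character_matrix(rows, ["c1"])
        assert initial_screen(m, CLADES) == []

    def test_modal_tie_skipped_with_trace(self):
        rows = voucher_rows(4, 4, "c1")
        rows[0] = ("a0", "A1", "cladeA", "adult", True, {"c1": "mid"})
        rows[1] = ("a1", "A1", "cladeA", "adult", True, {"c1": "mid"})
        # cladeA now 2 mid / 2 long: tie
        m = make_character_matrix(rows, ["c1"])
        trace = ScreeningTrace(stage="initial")
        assert initial_screen(m, CLADES, trace=trace) == []
        assert any("tie" in w for w in trace.warnings)

    def test_unknowns_excluded_from_constancy(self):
        rows = voucher_rows(6, 5, "c1")
        rows[0] = ("a0", "A1", "cladeA", "adult", True, {})  # unknown state
        m = make_character_matrix(rows, ["c1"])
        cands = initial_screen(m, CLADES)
        assert cands[0].n_scored["cladeA"] == 5

    def test_juveniles_excluded_by_default(self):
        rows = voucher_rows(5, 5, "c1")
        rows.append(("aj", "A1", "cladeA", "juvenile", True, {"c1": "short"}))
        m = make_character_matrix(rows, ["c1"])
        cands = initial_screen(m, CLADES)
        assert cands[0].constancy["cladeA"] == 1.0
        cands_all = initial_screen(m, CLADES, adults_only=False)
        assert cands_all[0].constancy["cladeA"] == pytest.approx(5 / 6)

    def test_missing_clade_is_error(self):
        m = make_character_matrix(voucher_rows(3, 3, "c1"), ["c1"])
        with pytest.raises(ValueError, match="cladeC"):
            initial_screen(m, ("cladeA", "cladeC"))


def block_scenario(n_match_a: int, n_block: int = 10):
    """Candidate at 9/10 vouchers, then one validation block with n_match_a matches."""
    rows = voucher_rows(10, 10, "c1")
    rows[0] = ("a0", "A1", "cladeA", "adult", True, {"c1": "short"})  # 9/10
    for i in range(n_block):
        state = "long" if i < n_match_a else "short"
        rows.append((f"av{i}", "A1", "cladeA", "adult", False, {"c1": state}))
    for i in range(n_block):
        rows.append((f"bv{i}", "B1", "cladeB", "adult", False, {"c1": "short"}))
    return make_character_matrix(rows, ["c1"])


class TestBlockValidate:
    def test_cumulative_retention_18_of_20(self):
        m = block_scenario(9)
        cands = initial_screen(m, CLADES)
        assert cands and cands[0].constancy["cladeA"] == pytest.approx(0.9)
        surv, trace = block_validate(cands, m, CLADES, block_size=10, seed=0)
        assert [c.character for c in surv] == ["c1"]
        assert surv[0].constancy["cladeA"] == pytest.approx(18 / 20)
        assert trace.blocks[0].decision == "retained"

    def test_cumulative_discard_15_of_20(self):
        m = block_scenario(6)
        cands = initial_screen(m, CLADES)
        surv, trace = block_validate(cands, m, CLADES, block_size=10, seed=0)
        assert surv == []
        rec = trace.blocks[0]
        assert rec.decision == "discarded" and rec.block_index == 1
        assert rec.cumulative_constancy["cladeA"] == pytest.approx(15 / 20)

    def test_same_seed_identical_trace(self):
        m = block_scenario(9)
        cands = initial_screen(m, CLADES)
        _, t1 = block_validate(cands, m, CLADES, seed=7)
        _, t2 = block_validate(cands, m, CLADES, seed=7)
        assert t1.to_table().equals(t2.to_table())

    def test_empty_validation_pool_passthrough(self):
        m = make_character_matrix(voucher_rows(5, 5, "c1"), ["c1"])
        cands = initial_screen(m, CLADES)
        surv, trace = block_validate(cands, m, CLADES)
        assert surv == cands
        assert any("empty validation pool" in w for w in trace.warnings)

    def test_discarded_character_never_reappears(self):
        """Once discarded at a block, a character has no records in later blocks."""
        m, _ = simulate_morphology(
            MorphScenario(
                seed=5,
                characters=(
                    CharacterSpec("good", "diagnostic", 0.97),
                    CharacterSpec("weak", "diagnostic", 0.72),
                ),
            ),
            clades=CLADES,
        )
        cands = [
            CandidateDiagnosis(
                character=name,
                modal_states={"cladeA": "s0", "cladeB": "s1"},
                constancy={"cladeA": 1.0, "cladeB": 1.0},
                n_scored={"cladeA": 5, "cladeB": 5},
                n_matched={"cladeA": 5, "cladeB": 5},
            )
            for name in ("good", "weak")
        ]
        _, trace = block_validate(cands, m, CLADES, seed=1)
        seen_blocks = {}
        for rec in trace.blocks:
            seen_blocks.setdefault(rec.character, []).append(
                (rec.block_index, rec.decision)
            )
        for char, recs in seen_blocks.items():
            discarded_at = [b for b, d in recs if d == "discarded"]
            if discarded_at:
                assert max(b for b, _ in recs) == min(discarded_at)

    def test_block_specimen_counts_conserve_pool(self):
        m, _ = simulate_morphology(MorphScenario(seed=9), clades=CLADES)
        cands = initial_screen(m, CLADES)
        assert cands
        char = cands[0].character
        surv, trace = block_validate([cands[0]], m, CLADES, seed=3)
        voucher_lots = {s.lot for s in m.specimens if s.molecular_voucher}
        for clade in CLADES:
            pool = [
                s for s in m.specimens
                if s.clade == clade and s.stage == "adult"
                and not s.molecular_voucher and s.lot in voucher_lots
            ]
            used = sum(
                rec.n_used[clade] for rec in trace.blocks if rec.character == char
            )
            if surv:  # character reached every block
                assert used == len(pool)


class TestFinalCheck:
    def survivor(self, n_matched=18, n_scored=20):
        return CandidateDiagnosis(
            character="c1",
            modal_states={"cladeA": "long", "cladeB": "short"},
            constancy={c: n_matched / n_scored for c in CLADES},
            n_scored={c: n_scored for c in CLADES},
            n_matched={c: n_matched for c in CLADES},
        )

    def holdout_matrix(self, n_match_a: int, n_holdout: int = 10):
        rows = voucher_rows(2, 2, "c1")  # voucher lots A1/B1
        for i in range(n_holdout):
            state = "long" if i < n_match_a else "short"
            rows.append((f"ah{i}", "A9", "cladeA", "adult", False, {"c1": state}))
            rows.append((f"bh{i}", "B9", "cladeB", "adult", False, {"c1": "short"}))
        return make_character_matrix(rows, ["c1"])

    def test_perfect_holdout_confirms(self):
        m = self.holdout_matrix(10)
        confirmed, trace = final_check([self.survivor()], m, CLADES, seed=0)
        assert [c.character for c in confirmed] == ["c1"]
        assert confirmed[0].constancy["cladeA"] == pytest.approx(28 / 30)

    def test_poor_holdout_removes_and_trace_names_block(self):
        # survivor carries 8/10; hold-out block 0/10 matching drags the
        # cumulative tally to 8/20 = 0.4 < 0.8
        m = self.holdout_matrix(0)
        weak = self.survivor(n_matched=8, n_scored=10)
        confirmed, trace = final_check([weak], m, CLADES, seed=0)
        assert confirmed == []
        assert trace.blocks[0].decision == "discarded"
        assert trace.blocks[0].block_index == 1
        assert trace.blocks[0].cumulative_constancy["cladeA"] == pytest.approx(0.4)

    def test_no_holdout_lots_warns_and_passes(self):
        m = make_character_matrix(voucher_rows(5, 5, "c1"), ["c1"])
        confirmed, trace = final_check([self.survivor()], m, CLADES, seed=0)
        assert [c.character for c in confirmed] == ["c1"]
        assert any("hold-out" in w for w in trace.warnings)


class TestScreenProperties:
    def test_threshold_monotonicity(self, rng):
        """A character surviving at a high threshold also survives at any lower one."""
        for s in range(20):
            m, _ = simulate_morphology(
                MorphScenario(seed=int(rng.integers(0, 2**31))), clades=CLADES
            )
            survivors = {}
            for thr in (0.9, 0.8, 0.7, 0.6):
                final, _ = run_screen(m, CLADES, threshold=thr, seed=s)
                survivors[thr] = {c.character for c in final}
            assert survivors[0.9] <= survivors[0.8] <= survivors[0.7] <= survivors[0.6]

    def test_zero_overlap_character_survives_any_threshold(self):
        m, _ = simulate_morphology(
            MorphScenario(
                seed=2, characters=(CharacterSpec("perfect", "diagnostic", 1.0),)
            ),
            clades=CLADES,
        )
        for thr in (0.5, 0.8, 0.99):
            final, _ = run_screen(m, CLADES, threshold=thr, seed=0)
            assert {c.character for c in final} == {"perfect"}

    def test_retention_rates_by_true_constancy(self):
        """c = 0.95 is nearly always retained, c = 0.60 essentially never."""
        kept = {0.95: 0, 0.60: 0}
        n_sims = 100
        for c_true in kept:
            for s in range(n_sims):
                m, _ = simulate_morphology(
                    MorphScenario(
                        seed=s,
                        characters=(CharacterSpec("x", "diagnostic", c_true),),
                    ),
                    clades=CLADES,
                )
                final, _ = run_screen(m, CLADES, seed=s)
                kept[c_true] += bool(final)
        assert kept[0.95] / n_sims >= 0.95
        assert kept[0.60] / n_sims <= 0.05


class TestCharacterMatrixIO:
    def test_csv_roundtrip(self, tmp_path):
        m, _ = simulate_morphology(MorphScenario(seed=1, n_per_clade=6), clades=CLADES)
        p = tmp_path / "m.csv"
        m.write_csv(p)
        back = CharacterMatrix.read_csv(p)
        assert back == m

    def test_single_clade_rejected(self):
        with pytest.raises(ValueError, match="2 clades"):
            make_character_matrix(
                [("a", "L", "x", "adult", True, {"c": "s"}),
                 ("b", "L", "x", "adult", True, {"c": "s"})],
                ["c"],
            )
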