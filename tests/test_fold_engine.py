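"""Folding engine vs independent oracles: enumeration, sampling, melting."""

import math

import numpy as np
import pytest

from riboscan.fold_engine import (
    CELSIUS_OFFSET,
    T37_K,
    EnergyModel,
    EngineError,
    EngineGuardError,
    NoMeltingTransition,
    NonCanonicalPairError,
    default_model,
)
from riboscan.rna_core import SecondaryStructure, parse_dotbracket, write_dotbracket

from conftest import brute_force_pairsets

TOY_SEQS = [
    "GGGAAAACCC",
    "GCGAAAACGC",
    "GGCAUAAGCC",
    "ACGUACGUACGU",
    "GGAAAACCAAGG",
]


class TestEvalEnergy:
    def test_open_chain_is_zero(self, engine):
        s = SecondaryStructure(length=6)
        assert engine.eval_energy("AAAAAA", s) == 0.0

    def test_hand_sum_from_shipped_table(self, engine, model):
        # (((....))) on GGGAAAACCC: two GC-on-GC stacks plus a 4-nt hairpin
        s = parse_dotbracket("(((....)))")
        expected = 2 * model.stack_dg("GC", "GC", T37_K) + model.hairpin_penalty(4)
        assert engine.eval_energy("GGGAAAACCC", s) == pytest.approx(expected)

    def test_multiloop_decomposition(self, engine, model):
        # (1,20) closes a multiloop holding the helices (2,10)-(4,8) and (12,18)-(13,17)
        seq = "GGGGAAACCCGGGAAACCCC"
        s = parse_dotbracket("((((...))).((...)).)")
        expected = (
            model.multiloop_penalty
            + 2 * model.stack_dg("GC", "GC", T37_K)  # (2,10)/(3,9) and (3,9)/(4,8)
            + model.stack_dg("GC", "GC", T37_K)  # (12,18)/(13,17)
            + 2 * model.hairpin_penalty(3)
        )
        assert engine.eval_energy(seq, s) == pytest.approx(expected)

    def test_bulge_and_internal_loops(self, engine, model):
        # 1-nt bulge: (1,10) around (3,9)
        e = engine.eval_energy("GAGAAAAACC", parse_dotbracket("(.(.....))"))
        assert e == pytest.approx(model.bulge_penalty(1) + model.hairpin_penalty(5))
        # 1x1 internal loop: (1,12) around (3,10)
        e = engine.eval_energy("GAGAAAAAACAC", parse_dotbracket("(.(......).)"))
        assert e == pytest.approx(
            model.internal_penalty(2) + model.hairpin_penalty(6)
        )

    def test_noncanonical_pair_identified(self, engine):
        s = SecondaryStructure.from_pairs(8, [(1, 8)])
        with pytest.raises(NonCanonicalPairError, match=r"\(1,8\)"):
            engine.eval_energy("AAAAAAAA", s)

    def test_mfe_energy_consistency(self, engine):
        for seq in TOY_SEQS:
            r = engine.mfe_fold(seq)
            assert engine.eval_energy(seq, r.structure) == pytest.approx(r.energy)

    def test_pk_bonus_term(self, model):
        import dataclasses

        from riboscan.fold_engine import FoldingEngine

        m2 = dataclasses.replace(model, pk_bonus_per_pair=-1.5)
        eng2 = FoldingEngine(m2)
        s = parse_dotbracket("((..[[..))..]]")
        seq = "GCAAGGAAGCAACC"  # (1,10)=GC, (2,9)=CG, pk (5,14)=GC, (6,13)=GC
        e_nested_only = eng2.eval_energy(
            seq, SecondaryStructure(length=14, nested_pairs=s.nested_pairs)
        )
        e_full = eng2.eval_energy(seq, s)
        assert e_full == pytest.approx(e_nested_only + 2 * (-1.5))


class TestMfeAndEnumeration:
    def test_no_pairs_possible(self, engine):
        r = engine.mfe_fold("AAAAAA")
        assert write_dotbracket(r.structure) == "......" and r.energy == 0.0

    def test_length4_single_structure(self, engine):
        out = engine.enumerate_structures("GGCC", math.inf)
        assert len(out) == 1 and out[0].structure.n_pairs == 0

    @pytest.mark.parametrize("seq", TOY_SEQS)
    def test_enumeration_complete_vs_bruteforce(self, engine, seq):
        ours = engine.enumerate_structures(seq, math.inf)
        oracle = brute_force_pairsets(seq)
        assert len(ours) == len(oracle)
        assert {frozenset((p.i, p.j) for p in r.structure.nested_pairs) for r in ours} == set(
            oracle
        )

    @pytest.mark.parametrize("seq", TOY_SEQS)
    def test_mfe_equals_enumeration_minimum(self, engine, seq):
        full = engine.enumerate_structures(seq, math.inf)
        r = engine.mfe_fold(seq)
        assert r.energy == pytest.approx(full[0].energy)
        assert r.structure == full[0].structure  # lexicographic tie-break agrees
        assert all(r.energy <= f.energy + 1e-9 for f in full)

    def test_delta_zero_returns_cooptimals_only(self, engine):
        out = engine.enumerate_structures("GGGAAAACCC", 0.0)
        e0 = out[0].energy
        assert all(abs(r.energy - e0) < 1e-9 for r in out)

    def test_enumeration_energy_agreement(self, engine):
        for r in engine.enumerate_structures("GCGAAAACGC", math.inf):
            assert engine.eval_energy("GCGAAAACGC", r.structure) == pytest.approx(
                r.energy
            )

    def test_guard(self, engine):
        with pytest.raises(EngineGuardError, match="external backend"):
            engine.enumerate_structures("A" * 41, 10.0)


class TestPartitionFunction:
    def test_unpairable_chain(self, engine):
        pf = engine.partition_function("AAAAAA")
        assert pf.Z == pytest.approx(1.0) and pf.G == pytest.approx(0.0)

    @pytest.mark.parametrize("seq", TOY_SEQS)
    def test_matches_enumeration_sum(self, engine, model, seq):
        RT = model.R * T37_K
        exact = sum(
            math.exp(-r.energy / RT)
            for r in engine.enumerate_structures(seq, math.inf)
        )
        pf = engine.partition_function(seq)
        assert pf.Z == pytest.approx(exact, rel=1e-6)

    def test_g_below_mfe(self, engine):
        for seq in TOY_SEQS:
            assert (
                engine.partition_function(seq).G
                <= engine.mfe_fold(seq).energy + 1e-9
            )
            assert engine.partition_function(seq).Z >= 1.0


class TestSampler:
    def test_unpairable_gives_open_chains(self, engine):
        out = engine.sample_boltzmann("AAAAAA", n=7, seed=3)
        assert len(out) == 7
        assert all(s.n_pairs == 0 for s in out)

    def test_seed_determinism(self, engine):
        a = engine.sample_boltzmann("GCGAAAACGC", n=50, seed=11)
        b = engine.sample_boltzmann("GCGAAAACGC", n=50, seed=11)
        assert [write_dotbracket(s) for s in a] == [write_dotbracket(s) for s in b]

    def test_invalid_n(self, engine):
        with pytest.raises(EngineError):
            engine.sample_boltzmann("GCGAAAACGC", n=0)

    def test_total_variation_against_exact_boltzmann(self, engine, model):
        seq = "GGGAAAACCC"
        RT = model.R * T37_K
        exact = {}
        for r in engine.enumerate_structures(seq, math.inf):
            exact[write_dotbracket(r.structure)] = math.exp(-r.energy / RT)
        Z = sum(exact.values())
        exact = {k: v / Z for k, v in exact.items()}
        n = 10_000
        counts: dict[str, int] = {}
        for s in engine.sample_boltzmann(seq, n=n, seed=202609):
            db = write_dotbracket(s)
            counts[db] = counts.get(db, 0) + 1
        assert set(counts) <= set(exact)  # sampler never leaves the ensemble
        tv = 0.5 * sum(
            abs(counts.get(k, 0) / n - p) for k, p in exact.items()
        )
        assert tv <= 0.05

    def test_probability_ordering(self, engine, model):
        # lower energy <=> higher exact Boltzmann probability
        seq = "GCGAAAACGC"
        RT = model.R * T37_K
        rs = engine.enumerate_structures(seq, math.inf)
        for a, b in zip(rs, rs[1:]):
            assert math.exp(-a.energy / RT) >= math.exp(-b.energy / RT)


class TestMelting:
    def test_no_transition(self, engine):
        with pytest.raises(NoMeltingTransition):
            engine.melting_temperature("AAAAAAAAAA")

    def test_matches_dense_grid_oracle(self, engine, model):
        """Independently recompute G(T) by summing over the brute-force
        structure list and locate the specific-heat maximum."""
        seq = "GGCGAAAACGCC"
        structs = [
            SecondaryStructure.from_pairs(len(seq), ps)
            for ps in brute_force_pairsets(seq)
        ]
        ts = np.arange(0.0, 150.0 + 0.5, 1.0)
        G = []
        for t in ts:
            T = t + CELSIUS_OFFSET
            RT = model.R * T
            z = sum(
                math.exp(-engine.eval_energy(seq, s, T) / RT) for s in structs
            )
            G.append(-RT * math.log(z))
        G = np.array(G)
        C = -(ts[1:-1] + CELSIUS_OFFSET) * (G[2:] - 2 * G[1:-1] + G[:-2])
        oracle_tm = float(ts[1:-1][int(np.argmax(C))])
        assert engine.melting_temperature(seq) == pytest.approx(oracle_tm)

    def test_gc_stem_melts_above_au_stem(self, engine):
        gc = engine.melting_temperature("GGGGGGGAAAACCCCCCC")
        au = engine.melting_temperature("AAAAAAAUUUUGUUUUUU")
        assert gc > au

    def test_ensemble_free_energy_nondecreasing_in_T(self, engine):
        """Relative to the 0-energy open chain, G rises toward 0 with
        temperature over the physical 0-100 C range (above ~110 C the
        temperature-independent loop penalties make the model re-entrant,
        which is outside its intended range)."""
        for seq in ("GCGAAAACGC", "GGGAAAACCC"):
            gs = [
                engine.partition_function(seq, t + CELSIUS_OFFSET).G
                for t in range(0, 101, 5)
            ]
            assert all(b >= a - 1e-9 for a, b in zip(gs, gs[1:]))


class TestEnergyModelIO:
    def test_yaml_roundtrip(self, model, tmp_path):
        path = tmp_path / "params.yaml"
        model.to_yaml(path)
        again = EnergyModel.from_yaml(path)
        assert again.stacks.keys() == model.stacks.keys()
        for k in model.stacks:
            assert again.stacks[k] == pytest.approx(model.stacks[k], abs=1e-3)
        assert again.hairpin_table == model.hairpin_table
        assert again.multiloop_penalty == model.multiloop_penalty

    def test_loop_extrapolation_monotone(self, model):
        assert model.hairpin_penalty(30) > model.hairpin_penalty(9)
        assert model.internal_penalty(40) > model.internal_penalty(6)
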