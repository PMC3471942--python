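import math

import numpy as np
import pytest

from thermoforest.annotations import ResidueState
from thermoforest.constants import PSSM_AA_ORDER
from thermoforest.fragments import (
    SEQ_FRAG_FEATURES,
    PotentialTable,
    build_occurrence_table,
    build_propensity_table,
    build_sequence_tables,
    fragment_state,
    score_sequence,
    seq_frag_features,
)
from thermoforest.records import ValidationError
from thermoforest.simulate import gen_corpora, gen_sequence


def _states(ss_string, exp_string):
    exp = {"b": "buried", "i": "intermediate", "e": "exposed"}
    return [ResidueState(ss3=s, exposure2="exposed" if e != "b" else "buried",
                         exposure3=exp[e])
            for s, e in zip(ss_string, exp_string)]


class TestOccurrenceTable:
    def test_identical_corpora_all_zero(self):
        corpus = ["MKVLATGH", "ACDEFGHI"]
        table = build_occurrence_table(corpus, list(corpus))
        assert table.default == 0
        assert all(v == 0 for v in table.values.values())

    def test_absent_fragment_closed_form(self):
        corpus_a, corpus_b = ["MKVLAT"], ["ACDEFGHI"]
        table = build_occurrence_table(corpus_a, corpus_b, pseudocount=1.0)
        na, nb, K = 3, 5, 20 ** 4
        assert table.value("WWWW") == pytest.approx(math.log(nb + K) - math.log(na + K))

    def test_brute_force_recount_oracle(self, rng):
        """Table values equal an independent count-and-log recomputation."""
        corpus_a = [gen_sequence(30, rng) for _ in range(3)]
        corpus_b = [gen_sequence(30, rng) for _ in range(3)]
        k, K = 0.5, 20 ** 4
        table = build_occurrence_table(corpus_a, corpus_b, pseudocount=k)

        def count(corpus):
            c = {}
            for seq in corpus:
                for i in range(len(seq) - 3):
                    c[seq[i:i + 4]] = c.get(seq[i:i + 4], 0) + 1
            return c, sum(c.values())

        ca, na = count(corpus_a)
        cb, nb = count(corpus_b)
        for frag in set(ca) | set(cb) | {"WWWW"}:
            expected = (math.log((ca.get(frag, 0) + k) / (na + k * K))
                        - math.log((cb.get(frag, 0) + k) / (nb + k * K)))
            assert table.value(frag) == pytest.approx(expected, abs=1e-12)

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValidationError):
            build_occurrence_table([], ["MKVLAT"])


class TestFragmentState:
    def test_majority(self):
        assert fragment_state(["H", "H", "H", "C"], ("H", "E", "C")) == "H"

    def test_tie_takes_third_residue(self):
        assert fragment_state(["H", "H", "E", "E"], ("H", "E", "C")) == "E"
        assert fragment_state(["E", "E", "H", "H"], ("H", "E", "C")) == "H"

    def test_unanimity(self):
        assert fragment_state(["C"] * 4, ("H", "E", "C")) == "C"


class TestStateTables:
    def test_all_helical_corpus(self):
        corpus = ["MKVLATGH", "ACDEFGHI"]
        other = ["WYWYWYWY", "LLLLKKKK"]
        helical = [_states("H" * 8, "e" * 8)] * 2
        with pytest.warns(UserWarning):
            sheet = build_occurrence_table(corpus, other, state="E",
                                           states_a=helical, states_b=helical)
        helix = build_occurrence_table(corpus, other, state="H",
                                       states_a=helical, states_b=helical)
        unconditioned = build_occurrence_table(corpus, other)
        for frag in set(helix.values) | set(unconditioned.values):
            assert helix.value(frag) == pytest.approx(unconditioned.value(frag))
        assert sheet.values == {} or all(v == sheet.default for v in sheet.values.values())

    def test_identical_corpora_state_tables_zero(self):
        corpus = ["MKVLATGH"]
        states = [_states("HHEECCHH", "bbiieebb")]
        tables = build_sequence_tables(corpus, list(corpus), states, list(states))
        for table in tables.values():
            assert table.default == pytest.approx(0)
            assert all(v == pytest.approx(0) for v in table.values.values())

    def test_propensity_hand_enumeration(self):
        """2-sequence toy with a 2-state annotation vs hand-computed values."""
        corpus_a, corpus_b = ["AAAAG"], ["GGGGA"]
        # fragments of corpus_a: AAAA (H-majority), AAAG (H); of b: GGGG, GGGA
        states_a = [_states("HHHHC", "eeeee")]
        states_b = [_states("HHCCC", "eeeee")]
        k, K = 1.0, 20 ** 4
        with pytest.warns(UserWarning, match="zero fragments"):
            table = build_propensity_table(corpus_a, corpus_b, states_a, states_b,
                                           state="H", pseudocount=k)
        # corpus_a: both fragments are H (majority H,H,H,H / H,H,H,C)
        # corpus_b: GGGG has states H,H,C,C -> tie, third residue C -> not H
        #           GGGA has states H,C,C,C -> C
        def lf(c, n):
            return math.log((c + k) / (n + k * K))
        va_AAAA = lf(1, 2) - lf(1, 2)
        vb_AAAA = lf(0, 0) - lf(0, 2)
        assert table.value("AAAA") == pytest.approx(va_AAAA - vb_AAAA)
        vb_GGGG = lf(0, 0) - lf(1, 2)
        va_GGGG = lf(0, 2) - lf(0, 2)
        assert table.value("GGGG") == pytest.approx(va_GGGG - vb_GGGG)


@pytest.fixture(scope="module")
def tables():
    corpus_a, corpus_b, states_a, states_b = gen_corpora(n_seqs=6, length=40, seed=5)
    return build_sequence_tables(corpus_a, corpus_b, states_a, states_b)


class TestSeqFragFeatures:
    def _random_case(self, rng, length=50, n_subs=1):
        letters = list(PSSM_AA_ORDER)
        wt = "".join(rng.choice(letters, size=length))
        positions = rng.choice(length, size=n_subs, replace=False)
        mut = list(wt)
        for pos in positions:
            mut[pos] = rng.choice([a for a in letters if a != wt[pos]])
        ss = rng.choice(["H", "E", "C"], size=length)
        rsa = rng.uniform(0, 1, size=length)
        states = _states("".join(ss),
                         "".join("b" if r < 0.25 else ("i" if r < 0.5 else "e")
                                 for r in rsa))
        return wt, "".join(mut), states

    def test_identity_all_zero(self, tables, rng):
        wt, _, states = self._random_case(rng)
        f = seq_frag_features(wt, wt, states, tables)
        assert set(f) == set(SEQ_FRAG_FEATURES)
        assert all(v == 0 for v in f.values())

    def test_antisymmetry_exact(self, tables, rng):
        for _ in range(25):
            wt, mut, states = self._random_case(rng, n_subs=int(rng.integers(1, 3)))
            fwd = seq_frag_features(wt, mut, states, tables)
            rev = seq_frag_features(mut, wt, states, tables)
            for name in fwd:
                assert rev[name] == -fwd[name]

    def test_locality_matches_full_rescore(self, tables, rng):
        for _ in range(25):
            wt, mut, states = self._random_case(rng, n_subs=int(rng.integers(1, 3)))
            local = seq_frag_features(wt, mut, states, tables)
            full = seq_frag_features(wt, mut, states, tables, local=False)
            for name in local:
                assert local[name] == pytest.approx(full[name], abs=1e-12)

    def test_full_rescore_uses_score_sequence(self, tables, rng):
        wt, mut, states = self._random_case(rng)
        table = tables[("occurrence", None)]
        full = score_sequence(mut, table, states) - score_sequence(wt, table, states)
        assert seq_frag_features(wt, mut, states, tables)["FBocc"] == \
               pytest.approx(full, abs=1e-12)

    def test_missing_table_errors(self, rng):
        wt, mut, states = self._random_case(rng)
        with pytest.raises(ValidationError, match="missing potential table"):
            seq_frag_features(wt, mut, states, {})


class TestSerialization:
    def test_roundtrip_and_determinism(self, tmp_path, rng):
        corpus_a = [gen_sequence(30, rng) for _ in range(3)]
        corpus_b = [gen_sequence(30, rng) for _ in range(3)]
        table = build_occurrence_table(corpus_a, corpus_b, meta={"source": "test"})
        p1, p2 = tmp_path / "t1.tsv", tmp_path / "t2.tsv"
        table.to_tsv(p1)
        rebuilt = build_occurrence_table(corpus_a, corpus_b, meta={"source": "test"})
        rebuilt.to_tsv(p2)
        assert p1.read_bytes() == p2.read_bytes()  # byte-identical builds
        back = PotentialTable.from_tsv(p1)
        assert back.values == table.values
        assert back.default == table.default
        assert back.kind == "occurrence" and back.state is None
        assert back.corpus_meta == {"source": "test"}
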