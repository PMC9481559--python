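"""Nearest-neighbor thermodynamics: hand-summation oracles over the shipped
tables, duplex symmetry, salt monotonicity and the exhaustive-register MFE
oracle."""

import hashlib
import math
import random
from importlib import resources

import pytest

from guideforge.io import reverse_complement
from guideforge.pool import CandidateSequence
from guideforge.thermo import (
    R_GAS,
    DuplexEnergy,
    ThermoConditions,
    dg_rna_dna_hybrid,
    dg_rna_rna_duplex,
    dna_duplex_energy,
    filter_by_hybrid_energy,
    load_nn_table,
    tm_dna_duplex,
)

TABLE_CHECKSUMS = {
    "nn_dna_dna.tsv": "cbac89b0852b8c188dc65671de5f969a015c2f7efecb935b749a33184910dc54",
    "nn_rna_dna.tsv": "7791d626405a971156bffdf35ff081b8269fe5c57c37d0a1510ee0e79090cf6d",
    "nn_rna_rna.tsv": "1284bc98f53d4a84e3f75bc360d72223b332548a6c2a96549ccd711376eb912d",
}


def _hand_sum(table, seq, extras=()):
    """Independent summation straight over the parsed table."""
    dh = sum(table.stacks[seq[i : i + 2]][0] for i in range(len(seq) - 1))
    ds = sum(table.stacks[seq[i : i + 2]][1] for i in range(len(seq) - 1))
    for key in extras:
        dh += table.extras[key][0]
        ds += table.extras[key][1]
    return dh, ds


class TestTableIntegrity:
    @pytest.mark.parametrize("kind", ["DNA_DNA", "RNA_DNA", "RNA_RNA"])
    def test_all_sixteen_steps_present(self, kind):
        table = load_nn_table(kind)
        alphabet = "ACGU" if kind != "DNA_DNA" else "ACGT"
        assert set(table.stacks) == {a + b for a in alphabet for b in alphabet}

    @pytest.mark.parametrize("kind", ["DNA_DNA", "RNA_RNA"])
    def test_reverse_complement_symmetry(self, kind):
        table = load_nn_table(kind)
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"} if kind == "DNA_DNA" else {
            "A": "U", "U": "A", "C": "G", "G": "C"
        }
        for step, value in table.stacks.items():
            rc = comp[step[1]] + comp[step[0]]
            assert table.stacks[rc] == value

    @pytest.mark.parametrize("filename,digest", sorted(TABLE_CHECKSUMS.items()))
    def test_shipped_table_checksums(self, filename, digest):
        data = resources.files("guideforge.data").joinpath(filename).read_bytes()
        assert hashlib.sha256(data).hexdigest() == digest


class TestDnaDuplex:
    def test_tm_equals_revcomp_tm(self):
        rng = random.Random(1)
        for _ in range(25):
            seq = "".join(rng.choice("ACGT") for _ in range(rng.randint(4, 23)))
            assert tm_dna_duplex(seq) == pytest.approx(
                tm_dna_duplex(reverse_complement(seq)), abs=1e-9
            )

    def test_ten_mer_matches_hand_summation(self):
        seq = "ACGTTGCAGT"
        table = load_nn_table("DNA_DNA")
        dh, ds = _hand_sum(table, seq, extras=("init_AT", "init_AT"))
        energy = dna_duplex_energy(seq)
        assert energy.dh == pytest.approx(dh)
        assert energy.ds == pytest.approx(ds)  # 1 M Na+: zero salt correction

    def test_self_complementary_correction_applied(self):
        seq = "GAATTC"
        table = load_nn_table("DNA_DNA")
        dh, ds = _hand_sum(table, seq, extras=("init_GC", "init_GC", "sym"))
        energy = dna_duplex_energy(seq)
        assert (energy.dh, energy.ds) == (pytest.approx(dh), pytest.approx(ds))

    def test_tm_strictly_increases_with_salt(self):
        rng = random.Random(2)
        for _ in range(30):
            seq = "".join(rng.choice("ACGT") for _ in range(12))
            tms = [
                tm_dna_duplex(seq, ThermoConditions(na_molar=na))
                for na in (0.05, 0.2, 1.0)
            ]
            assert tms[0] < tms[1] < tms[2]

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            tm_dna_duplex("A")

    def test_dg_dh_ds_consistency(self):
        energy = dna_duplex_energy("ACGTACGTTT")
        assert energy.dg == pytest.approx(energy.dh - 310.15 * energy.ds / 1000, abs=0.05)


class TestRnaDnaHybrid:
    def test_six_mer_matches_hand_summation(self):
        seq = "ACGUAC"
        table = load_nn_table("RNA_DNA")
        dh, ds = _hand_sum(table, seq, extras=("init",))
        energy = dg_rna_dna_hybrid(seq)
        assert energy.dh == pytest.approx(dh)
        assert energy.ds == pytest.approx(ds)
        assert energy.dg == pytest.approx(dh - 310.15 * ds / 1000, abs=1e-9)

    def test_additivity_of_one_extra_step(self):
        base, longer = "ACGUA", "ACGUAC"
        table = load_nn_table("RNA_DNA")
        step_dh, step_ds = table.stacks["AC"]
        e0, e1 = dg_rna_dna_hybrid(base), dg_rna_dna_hybrid(longer)
        assert e1.dh - e0.dh == pytest.approx(step_dh)
        assert e1.ds - e0.ds == pytest.approx(step_ds)

    def test_au_weaker_than_gc(self):
        au = dg_rna_dna_hybrid("AUAUAUAU").dg
        gc = dg_rna_dna_hybrid("GCGCGCGC").dg
        assert au > gc

    def test_hybrid_is_asymmetric(self):
        assert dg_rna_dna_hybrid("AACGU").dg != pytest.approx(
            dg_rna_dna_hybrid("UGCAA").dg
        )

    def test_non_rna_rejected(self):
        with pytest.raises(ValueError):
            dg_rna_dna_hybrid("ACGT")

    def test_split_additivity(self):
        """Splitting at an internal step and recombining reproduces the full
        stack sum."""
        seq = "ACGUACGUAC"
        table = load_nn_table("RNA_DNA")
        init = table.extras["init"]
        k = 4
        full = dg_rna_dna_hybrid(seq)
        left, right = dg_rna_dna_hybrid(seq[: k + 1]), dg_rna_dna_hybrid(seq[k:])
        assert left.dh + right.dh - init[0] == pytest.approx(full.dh, abs=1e-9)
        assert left.ds + right.ds - init[1] == pytest.approx(full.ds, abs=1e-9)


def brute_force_register_mfe(a, b, conditions=ThermoConditions()):
    """Independent oracle: explicit pair list per register, stacks summed."""
    table = load_nn_table("RNA_RNA")
    wc = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
    wob = {("G", "U"), ("U", "G")}
    t = conditions.temp_c + 273.15

    def dg(dh, ds):
        return dh - t * ds / 1000

    best = dg(*table.extras["init"])
    for offset in range(-(len(b) - 1), len(a)):
        pairs = []
        for i in range(len(a)):
            j = len(b) - 1 - (i - offset)  # antiparallel partner in b
            if 0 <= j < len(b):
                pairs.append((i, (a[i], b[j])))
        dh, ds = table.extras["init"]
        for (i1, p1), (i2, p2) in zip(pairs, pairs[1:]):
            if i2 == i1 + 1 and (p1 in wc | wob) and (p2 in wc | wob):
                if p1 in wob or p2 in wob:
                    sh, ss = table.extras["wobble"]
                else:
                    sh, ss = table.stacks[a[i1] + a[i2]]
                dh, ds = dh + sh, ds + ss
        best = min(best, dg(dh, ds))
    return best


class TestRnaRnaDuplex:
    def test_symmetry(self):
        rng = random.Random(3)
        for _ in range(20):
            a = "".join(rng.choice("ACGU") for _ in range(rng.randint(2, 10)))
            b = "".join(rng.choice("ACGU") for _ in range(rng.randint(2, 10)))
            assert dg_rna_rna_duplex(a, b).dg == pytest.approx(
                dg_rna_rna_duplex(b, a).dg, abs=1e-9
            )

    def test_gc_duplex_matches_hand_summation(self):
        table = load_nn_table("RNA_RNA")
        dh = 4 * table.stacks["GG"][0] + table.extras["init"][0]
        ds = 4 * table.stacks["GG"][1] + table.extras["init"][1]
        energy = dg_rna_rna_duplex("GGGGG", "CCCCC")
        assert energy.dh == pytest.approx(dh)
        assert energy.ds == pytest.approx(ds)

    def test_matches_exhaustive_register_oracle(self):
        rng = random.Random(4)
        for _ in range(150):
            a = "".join(rng.choice("ACGU") for _ in range(rng.randint(1, 8)))
            b = "".join(rng.choice("ACGU") for _ in range(rng.randint(1, 8)))
            assert dg_rna_rna_duplex(a, b).dg == pytest.approx(
                brute_force_register_mfe(a, b), abs=1e-9
            ), (a, b)

    def test_no_complementarity_returns_initiation_penalty(self):
        table = load_nn_table("RNA_RNA")
        init_dg = table.extras["init"][0] - 310.15 * table.extras["init"][1] / 1000
        assert dg_rna_rna_duplex("AAAA", "AAAA").dg == pytest.approx(init_dg)
        assert dg_rna_rna_duplex("GGGG", "CCCC").dg < 0


class TestHybridFilter:
    @staticmethod
    def _cands():
        out = []
        for i, spacer in enumerate(
            ["GC" * 11 + "G", "AT" * 11 + "A", "ACGT" * 5 + "ACG"], start=1
        ):
            out.append(
                CandidateSequence(
                    id=f"g{i}", spacer=spacer, repeat_spacer_rna="", tm=None
                )
            )
        return out

    def test_unbounded_range_retains_all(self):
        retained, rejected = filter_by_hybrid_energy(
            self._cands(), (-math.inf, math.inf)
        )
        assert len(retained) == 3 and not rejected
        assert all(c.hybrid_dg is not None for c in retained)

    def test_inclusive_boundary(self):
        cands = self._cands()
        filter_by_hybrid_energy(cands, (-math.inf, math.inf))
        dg = cands[0].hybrid_dg
        retained, _ = filter_by_hybrid_energy([cands[0]], (dg, dg))
        assert retained == [cands[0]]

    def test_partition_law(self):
        cands = self._cands()
        retained, rejected = filter_by_hybrid_energy(cands, (-30.0, -25.0))
        assert sorted(c.id for c in retained + rejected) == [c.id for c in cands]
        assert not (set(c.id for c in retained) & set(c.id for c in rejected))

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            filter_by_hybrid_energy(self._cands(), (-5.0, -20.0))
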