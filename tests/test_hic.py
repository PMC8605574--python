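"""Digestion, fragment assignment, pair classification, binning, balancing."""

import numpy as np
import pandas as pd
import pytest

from telomap import (
    GenomeAssembly,
    SyntheticConfig,
    assign_fragment,
    assign_fragments,
    balance,
    bin_pairs,
    classify_pairs,
    digest,
    make_genome,
    make_hic_pairs,
    rebalance,
)
from telomap.genome import GenomeError
from telomap.hic import NON_LIGATION, SELF_LIGATION, VALID, ContactMatrix


def asm_from_seqs(**seqs):
    return GenomeAssembly({k: len(v) for k, v in seqs.items()}, seqs)


def pair_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2", "read_len"],
    )


class TestDigest:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("AAAGATCAAA", [(0, 3), (3, 10)]),
            ("GATCGATC", [(0, 4), (4, 8)]),
            ("AAAAAAA", [(0, 7)]),  # motif-free: single fragment
            ("GATCAAAA", [(0, 8)]),  # cut at position 0 is a no-op
        ],
    )
    def test_cut_before_motif(self, seq, expected):
        rmap = digest(asm_from_seqs(c=seq))
        frags = [(f.start, f.end) for f in rmap.fragments("c")]
        assert frags == expected

    def test_fragments_partition_chromosome(self, small_genome):
        _, assembly, _ = small_genome
        rmap = digest(assembly)
        for chrom in assembly.chrom_names:
            frags = rmap.fragments(chrom)
            assert frags[0].start == 0
            assert frags[-1].end == assembly.chrom_lengths[chrom]
            for a, b in zip(frags, frags[1:]):
                assert a.end == b.start


class TestAssignFragment:
    def test_cut_site_goes_downstream(self):
        rmap = digest(asm_from_seqs(c="AAAGATCAAA"))
        assert assign_fragment(rmap, "c", 2) == 0
        assert assign_fragment(rmap, "c", 3) == 1  # exactly on the cut
        assert assign_fragment(rmap, "c", 0) == 0

    def test_out_of_bounds(self):
        rmap = digest(asm_from_seqs(c="AAAGATCAAA"))
        with pytest.raises(GenomeError):
            assign_fragment(rmap, "c", 10)

    def test_linear_scan_oracle(self, small_genome, rng):
        _, assembly, _ = small_genome
        rmap = digest(assembly)
        chroms = []
        positions = []
        for _ in range(10_000):
            c = assembly.chrom_names[int(rng.integers(len(assembly.chrom_names)))]
            chroms.append(c)
            positions.append(int(rng.integers(0, assembly.chrom_lengths[c])))
        got = assign_fragments(rmap, chroms, np.array(positions))
        frag_lists = {c: rmap.fragments(c) for c in assembly.chrom_names}
        for k in range(0, 10_000, 7):  # oracle spot-grid over the batch
            c, p = chroms[k], positions[k]
            expected = next(
                i + rmap.frag_offsets[c]
                for i, f in enumerate(frag_lists[c])
                if f.start <= p < f.end
            )
            assert got[k] == expected


class TestClassifyPairs:
    def test_class_rules(self):
        # chrom "c": fragments [0,3) and [3,10)
        asm = asm_from_seqs(c="AAAGATCAAA")
        rmap = digest(asm)
        pairs = pair_frame(
            [
                ("c", 0, "+", "c", 5, "-", 1),  # different fragments -> valid
                ("c", 4, "+", "c", 8, "-", 1),  # same frag, inward -> non-ligation
                ("c", 8, "-", "c", 4, "+", 1),  # same, inward (order swapped)
                ("c", 4, "-", "c", 8, "+", 1),  # same, divergent -> self-ligation
                ("c", 4, "+", "c", 8, "+", 1),  # same, equal strands -> self-ligation
            ]
        )
        df, census = classify_pairs(pairs, rmap)
        assert list(df["pair_class"]) == [
            VALID, NON_LIGATION, NON_LIGATION, SELF_LIGATION, SELF_LIGATION,
        ]
        assert census == {VALID: 1, NON_LIGATION: 2, SELF_LIGATION: 2}

    def test_synthetic_pairs_mostly_valid(self, small_genome):
        cfg, assembly, planted = small_genome
        pairs, _ = make_hic_pairs(assembly, planted, cfg)
        _, census = classify_pairs(pairs, digest(assembly))
        assert census[VALID] / len(pairs) >= 0.95


class TestBinPairs:
    def test_read_inside_one_bin(self):
        asm = GenomeAssembly({"c": 30_000})
        pairs = pair_frame([("c", 100, "+", "c", 20_100, "+", 75)])
        cm = bin_pairs(pairs, asm, bin_size=10_000)
        assert cm.matrix[0, 2] == pytest.approx(1.0)
        assert cm.matrix[2, 0] == pytest.approx(1.0)
        assert cm.total_mass() == pytest.approx(1.0)

    def test_boundary_split_30_45(self):
        """Read spanning a bin boundary 30 bp / 45 bp splits 0.4 / 0.6."""
        asm = GenomeAssembly({"c": 30_000})
        pairs = pair_frame([("c", 9_970, "+", "c", 25_000, "+", 75)])
        cm = bin_pairs(pairs, asm, bin_size=10_000)
        assert cm.matrix[0, 2] == pytest.approx(0.4)
        assert cm.matrix[1, 2] == pytest.approx(0.6)
        assert cm.total_mass() == pytest.approx(1.0)

    def test_minus_strand_span_extends_left(self):
        asm = GenomeAssembly({"c": 30_000})
        # '-' read at 10_029 covers [9_955, 10_030): 45 bp left, 30 bp right
        pairs = pair_frame([("c", 10_029, "-", "c", 25_000, "+", 75)])
        cm = bin_pairs(pairs, asm, bin_size=10_000)
        assert cm.matrix[0, 2] == pytest.approx(0.6)
        assert cm.matrix[1, 2] == pytest.approx(0.4)

    def test_mass_conservation_synthetic(self, small_genome):
        cfg, assembly, planted = small_genome
        pairs, _ = make_hic_pairs(assembly, planted, cfg)
        df, _ = classify_pairs(pairs, digest(assembly))
        valid = df[df["pair_class"] == VALID]
        cm = bin_pairs(valid, assembly, cfg.hic_bin_bp)
        assert cm.total_mass() == pytest.approx(len(valid), rel=1e-9)

    def test_order_invariance(self, small_genome):
        cfg, assembly, planted = small_genome
        small = SyntheticConfig(**{**cfg.__dict__, "n_pairs": 5_000})
        pairs, _ = make_hic_pairs(assembly, planted, small)
        cm1 = bin_pairs(pairs, assembly, 10_000)
        cm2 = bin_pairs(pairs.sample(frac=1, random_state=0), assembly, 10_000)
        assert np.allclose(cm1.matrix, cm2.matrix)


class TestBalance:
    def test_uniform_two_by_two(self):
        cm = ContactMatrix(np.ones((2, 2)), 10, ["a", "b"], {"a": 10, "b": 10})
        bal = balance(cm)
        assert np.allclose(bal.matrix, 0.5)
        assert bal.state == "balanced"

    def test_row_sums_and_idempotence(self, rng):
        n = 50
        m = rng.random((n, n)) + 0.05
        m = (m + m.T) / 2
        cm = ContactMatrix(m, 10, ["c"], {"c": n * 10})
        bal = balance(cm, tol=1e-10)
        sums = bal.matrix.sum(axis=1)
        assert np.abs(sums - 1).max() < 1e-10
        again = rebalance(bal, tol=1e-10)
        assert np.allclose(again.matrix, bal.matrix, atol=1e-9)
        assert again.balance_iterations == 1

    def test_symmetry_preserved(self, rng):
        m = rng.random((30, 30))
        m = m @ m.T  # positive semidefinite symmetric, strictly positive
        cm = ContactMatrix(m, 10, ["c"], {"c": 300})
        bal = balance(cm)
        assert np.array_equal(bal.matrix, bal.matrix.T)

    def test_zero_rows_masked_and_left_zero(self, rng):
        m = rng.random((10, 10)) + 0.1
        m = (m + m.T) / 2
        m[3, :] = 0
        m[:, 3] = 0
        cm = ContactMatrix(m, 10, ["c"], {"c": 100})
        bal = balance(cm)
        assert not bal.mask[3]
        assert np.all(bal.matrix[3] == 0)
        sums = bal.matrix[bal.mask].sum(axis=1)
        assert np.abs(sums - 1).max() < 1e-8
        assert np.isnan(bal.contact_probability(3, 5))
        assert bal.contact_probability(2, 5) == bal.contact_probability(5, 2)

    def test_alternating_normalization_oracle(self):
        """Symmetric single-vector scaling matches naive row/col alternation."""
        for trial in range(10):
            rng = np.random.default_rng(500 + trial)
            n = 50
            m = rng.random((n, n)) + 0.02
            m = (m + m.T) / 2
            cm = ContactMatrix(m, 10, ["c"], {"c": n * 10})
            bal = balance(cm, tol=1e-12, max_iter=2000)

            x = m.copy()
            for _ in range(10_000):
                x = x / x.sum(axis=1, keepdims=True)
                x = x / x.sum(axis=0, keepdims=True)
                if np.abs(x.sum(axis=1) - 1).max() < 1e-13:
                    break
            assert np.abs(bal.matrix - x).max() < 1e-6

    def test_raw_state_required(self, rng):
        m = (lambda a: (a + a.T) / 2)(rng.random((4, 4)))
        cm = ContactMatrix(m, 10, ["c"], {"c": 40}, state="balanced")
        with pytest.raises(Exception):
            balance(cm)

    def test_nonconvergence_flagged(self, rng):
        m = rng.random((20, 20)) + 0.1
        m = (m + m.T) / 2
        cm = ContactMatrix(m, 10, ["c"], {"c": 200})
        with pytest.warns(RuntimeWarning):
            bal = balance(cm, tol=1e-14, max_iter=2)
        assert not bal.converged


class TestMatrixIO:
    def test_text_round_trip(self, small_genome):
        cfg, assembly, planted = small_genome
        small = SyntheticConfig(**{**cfg.__dict__, "n_pairs": 20_000})
        pairs, _ = make_hic_pairs(assembly, planted, small)
        cm = balance(bin_pairs(pairs, assembly, 10_000))
        import io, tempfile, os
        from pathlib import Path
        with tempfile.TemporaryDirectory() as d:
            p = Path(d) / "m.txt"
            cm.write_text(p)
            back = ContactMatrix.read_text(p)
        assert back.bin_size == cm.bin_size
        assert back.state == "balanced"
        assert np.allclose(back.matrix, cm.matrix)
        assert np.array_equal(back.mask, cm.mask)

    def test_ground_truth_correlation(self, small_genome):
        """Balanced sampled matrix tracks the balanced ground-truth map."""
        cfg, assembly, planted = small_genome
        pairs, truth = make_hic_pairs(assembly, planted, cfg)
        df, _ = classify_pairs(pairs, digest(assembly))
        valid = df[df["pair_class"] == VALID]
        bal = balance(bin_pairs(valid, assembly, cfg.hic_bin_bp))
        gt = ContactMatrix(
            truth.weight_matrix, cfg.hic_bin_bp, assembly.chrom_names,
            assembly.chrom_lengths,
        )
        gt_bal = balance(gt)
        iu = np.triu_indices(bal.n_bins, k=1)
        r = np.corrcoef(bal.matrix[iu], gt_bal.matrix[iu])[0, 1]
        assert r > 0.9
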