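"""Synthetic genomes, strains, reads, and the assembly emulator."""

import numpy as np
import pytest
from scipy.stats import binom

from aninull._encoding import revcomp
from aninull.simulate import (AssemblyEmulationModel, Genome, MutationLog,
                              derive_strain, emulate_assembly,
                              generate_ancestor, hamming_identity,
                              simulate_reads)


def naive_replay(parent: str, events) -> str:
    """Independent event-by-event replay oracle (character lists)."""
    chars = list(parent)
    out = []
    i = 0
    for pos, etype, payload in events:
        out.extend(chars[i:pos])
        if etype == "SNV":
            out.append(payload)
            i = pos + 1
        elif etype == "insertion":
            out.extend(payload)
            i = pos
        else:
            i = pos + int(payload)
    out.extend(chars[i:])
    return "".join(out)


class TestAncestor:
    def test_gc_fraction_within_binomial_interval(self):
        g = generate_ancestor(100_000, 0.37, seed=1)
        gc = (g.seq.count("G") + g.seq.count("C"))
        lo, hi = binom.ppf([0.005, 0.995], 100_000, 0.37)
        assert lo <= gc <= hi

    def test_deterministic_under_seed(self):
        assert generate_ancestor(5000, 0.5, seed=9).seq == \
            generate_ancestor(5000, 0.5, seed=9).seq

    @pytest.mark.parametrize("kwargs", [dict(length=0, gc_fraction=0.5),
                                        dict(length=100, gc_fraction=0.0),
                                        dict(length=100, gc_fraction=1.0)])
    def test_invalid_parameters(self, kwargs):
        with pytest.raises(ValueError):
            generate_ancestor(seed=0, **kwargs)


class TestDeriveStrain:
    def test_zero_rates_identity(self, ancestor):
        child, log = derive_strain(ancestor, 0.0, 0.0, seed=1)
        assert child.seq == ancestor.seq
        assert log.events == []

    def test_snv_count_within_binomial_interval(self):
        g = generate_ancestor(100_000, 0.42, seed=2)
        _, log = derive_strain(g, 0.01, 0.0, seed=3)
        lo, hi = binom.ppf([0.005, 0.995], 100_000, 0.01)
        assert lo <= log.snv_count <= hi

    def test_replay_oracle_many_draws(self):
        rng = np.random.default_rng(11)
        parent = generate_ancestor(2000, 0.42, seed=12)
        for i in range(100):
            snv = float(rng.uniform(0, 0.05))
            indel = float(rng.uniform(0, 0.02))
            child, log = derive_strain(parent, snv, indel, seed=1000 + i)
            assert naive_replay(parent.seq, log.events) == child.seq

    def test_positions_strictly_increasing(self, ancestor):
        _, log = derive_strain(ancestor, 0.01, 0.002, seed=4)
        positions = [p for p, _, _ in log.events]
        assert all(b > a for a, b in zip(positions, positions[1:]))

    def test_rate_out_of_range(self, ancestor):
        with pytest.raises(ValueError):
            derive_strain(ancestor, 0.5, 0.0, seed=0)

    def test_hamming_identity_rejects_indel_logs(self, ancestor):
        _, log = derive_strain(ancestor, 0.0, 0.01, seed=5)
        with pytest.raises(ValueError):
            hamming_identity(ancestor, log)


class TestSimulateReads:
    def test_error_free_reads_are_genome_substrings(self, ancestor):
        reads = simulate_reads(ancestor, 200, error_rate=0.0, seed=6)
        assert len(reads) == 200
        for r1, r2 in reads.pairs:
            assert r1.seq in ancestor.seq
            assert revcomp(r2.seq) in ancestor.seq

    def test_observed_error_rate_matches(self, ancestor):
        # 7,000 pairs x 300 bases = 2.1 Mb simulated
        rate = 0.004
        reads = simulate_reads(ancestor, 7000, error_rate=rate, seed=8)
        clean = simulate_reads(ancestor, 7000, error_rate=0.0, seed=8)
        mism = total = 0
        for (a1, a2), (b1, b2) in zip(reads.pairs, clean.pairs):
            mism += sum(x != y for x, y in zip(a1.seq, b1.seq))
            mism += sum(x != y for x, y in zip(a2.seq, b2.seq))
            total += len(a1.seq) + len(a2.seq)
        se = (rate * (1 - rate) / total) ** 0.5
        assert abs(mism / total - rate) <= 3 * se

    def test_insert_longer_than_genome_rejected(self):
        g = Genome(seq="ACGT" * 50, label="tiny")
        with pytest.raises(ValueError):
            simulate_reads(g, 10, read_len=150, insert_mean=400, seed=0)


class TestEmulateAssembly:
    def test_noise_free_contigs_cover_genome_in_order(self, ancestor):
        model = AssemblyEmulationModel(base_error_rate=0.0, min_contig_len=1)
        asm = emulate_assembly(ancestor, model, seed=13)
        cursor = 0
        for contig in asm.contigs:
            pos = ancestor.seq.find(contig.seq, cursor)
            assert pos >= 0, "contig is not an in-order genome substring"
            cursor = pos + len(contig.seq)

    def test_deterministic_under_seed(self, ancestor):
        model = AssemblyEmulationModel()
        a = emulate_assembly(ancestor, model, seed=14)
        b = emulate_assembly(ancestor, model, seed=14)
        assert a.sequences() == b.sequences()

    def test_zero_depth_gives_empty_assembly(self, ancestor, caplog):
        model = AssemblyEmulationModel(mean_depth=0.0)
        with caplog.at_level("WARNING"):
            asm = emulate_assembly(ancestor, model, seed=15)
        assert len(asm) == 0

    def test_consensus_error_decreases_with_depth(self):
        model = AssemblyEmulationModel(base_error_rate=0.05)
        p = model.consensus_error_prob
        assert p(20) < p(5) < p(1)
        # non-increasing along each depth parity
        odds = [p(d) for d in range(1, 30, 2)]
        evens = [p(d) for d in range(2, 30, 2)]
        for seq in (odds, evens):
            assert all(b <= a for a, b in zip(seq, seq[1:]))

    def test_emulated_mismatch_rate_tracks_model(self, ancestor):
        # realized consensus errors agree with the analytic per-depth
        # probabilities to within binomial noise
        model = AssemblyEmulationModel(min_contig_len=1)
        asm = emulate_assembly(ancestor, model, seed=16)
        mism = 0
        for contig in asm.contigs:
            src = contig.description.split("=")[1]
            start, stop = map(int, src.split(":")[1].split("-"))
            mism += sum(x != y for x, y in
                        zip(contig.seq, ancestor.seq[start:stop]))
        from scipy.stats import poisson

        exp_rate = sum(poisson.pmf(d, model.mean_depth)
                       * model.consensus_error_prob(d) for d in range(40))
        n = asm.total_length
        se = (exp_rate * (1 - exp_rate) / n) ** 0.5
        # cluster-corrected tolerance: errors arrive in low-depth windows
        assert abs(mism / n - exp_rate) <= 30 * se
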