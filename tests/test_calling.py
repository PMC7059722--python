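"""Genome binning, PET counting, background sampling and the caller."""

import numpy as np
import pandas as pd
import pytest

from capture3c.calling import (
    CallConfig,
    ContactIndex,
    InteractionModel,
    bin_genome,
    capture_rate,
    count_pets,
    merge_se_baits,
    sample_background,
)
from capture3c.genome import Genome, GenomicInterval
from capture3c.pets import PAIR_COLUMNS, BaitRegion

from conftest import contacts_without_self_ligations


class TestBinGenome:
    def test_tiling_with_short_tail(self):
        grid = bin_genome(Genome({"c": 1000}), 300)
        ivs = [grid.bin_interval("c", k) for k in range(grid.n_bins("c"))]
        assert [(v.start, v.end) for v in ivs] == [
            (0, 300), (300, 600), (600, 900), (900, 1000)
        ]

    def test_exact_fit_single_bin(self):
        grid = bin_genome(Genome({"c": 300}), 300)
        assert grid.n_bins("c") == 1
        assert grid.bin_interval("c", 0).end == 300

    def test_total_bp_conserved_on_random_genomes(self, rng):
        for _ in range(20):
            genome = Genome(
                {f"c{i}": int(rng.integers(100, 100_000)) for i in range(4)}
            )
            bin_size = int(rng.integers(1, 5000))
            grid = bin_genome(genome, bin_size)
            total = sum(
                grid.bin_interval(c, k).length
                for c in genome for k in range(grid.n_bins(c))
            )
            assert total == genome.total_bp

    def test_nonpositive_bin_size_rejected(self):
        with pytest.raises(ValueError):
            bin_genome(Genome({"c": 100}), 0)


def pet_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["bait_id", "bait_chrom", "bait_pos", "chrom", "pos",
                 "distance", "is_trans", "bait_bait", "pair_index"],
    )


class TestCountPets:
    def test_simple_tally(self):
        grid = bin_genome(Genome({"c": 1000}), 300)
        pets = pet_frame(
            [("b", "c", 0, "c", p, 0.0, False, False, i)
             for i, p in enumerate([10, 150, 310])]
        )
        assert count_pets(pets, grid) == {("c", 0): 2, ("c", 1): 1}

    def test_empty_gives_empty(self):
        grid = bin_genome(Genome({"c": 1000}), 300)
        assert count_pets(pet_frame([]), grid) == {}

    def test_matches_brute_force_tally(self, rng):
        genome = Genome({"c1": 50_000, "c2": 30_000})
        grid = bin_genome(genome, 700)
        rows = []
        for i in range(10_000):
            chrom = "c1" if rng.random() < 0.6 else "c2"
            pos = int(rng.integers(0, genome[chrom]))
            rows.append(("b", "c1", 0, chrom, pos, 0.0, False, False, i))
        pets = pet_frame(rows)
        out = count_pets(pets, grid)
        brute: dict = {}
        for _, r in pets.iterrows():
            key = (r["chrom"], r["pos"] // 700)
            brute[key] = brute.get(key, 0) + 1
        assert out == brute
        assert sum(out.values()) == len(pets)

    def test_off_genome_position_rejected(self):
        grid = bin_genome(Genome({"c": 1000}), 100)
        with pytest.raises(ValueError):
            count_pets(pet_frame([("b", "c", 0, "c", 5000, 0.0, False, False, 0)]), grid)


def uniform_contacts(rng, genome, n, max_gap=200_000):
    """Uniform contact field: anchors uniform, partners uniform within max_gap."""
    rows = []
    chroms = list(genome)
    for i in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        M = genome[chrom]
        a = int(rng.integers(0, M))
        b = int(np.clip(a + rng.integers(-max_gap, max_gap + 1), 0, M - 1))
        rows.append((f"r{i}", chrom, a, 60, chrom, b, 60))
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


class TestSampleBackground:
    def test_empty_contact_set_degenerate(self, small_genome, two_baits):
        empty = pd.DataFrame([], columns=PAIR_COLUMNS)
        idx = ContactIndex(empty, small_genome)
        bg = sample_background(
            two_baits[0].interval,
            GenomicInterval("chr1", 700_000, 705_000),
            idx, two_baits, small_genome, n=2000, seed=1,
        )
        assert bg.kind == "point_mass"
        assert bg.p_less(1) == 1.0

    def test_deterministic_under_seed(self, rng, small_genome, two_baits):
        contacts = uniform_contacts(rng, small_genome, 20_000)
        idx = ContactIndex(contacts, small_genome)
        args = (
            two_baits[0].interval, GenomicInterval("chr1", 700_000, 705_000),
            idx, two_baits, small_genome,
        )
        a = sample_background(*args, n=3000, seed=42, store_counts=True)
        b = sample_background(*args, n=3000, seed=42, store_counts=True)
        assert np.array_equal(a.counts, b.counts)
        assert (a.kind, a.r, a.p, a.lam) == (b.kind, b.r, b.p, b.lam)

    def test_uniform_density_expectation(self, rng, small_genome, two_baits):
        # uniform partner within +/- D of a uniform anchor: a placed pair of
        # two L-intervals at distance d < D expects about
        # n * 2 * (L/G) * (L / 2D) counted contacts
        D = 200_000
        n_contacts = 100_000
        contacts = uniform_contacts(rng, small_genome, n_contacts, max_gap=D)
        idx = ContactIndex(contacts, small_genome)
        L = 5_000
        d = 80_000
        bg = sample_background(
            GenomicInterval("chr1", 100_000, 100_000 + L),
            GenomicInterval("chr1", 100_000 + d, 100_000 + d + L),
            idx, [], small_genome, n=5000, seed=7, store_counts=True,
        )
        G = small_genome.total_bp
        expected = n_contacts * 2 * (L / G) * (L / (2 * D))
        se = np.sqrt(bg.counts.var() / len(bg.counts))
        assert abs(bg.mean - expected) < 3 * se + 0.02 * expected

    def test_inter_chromosomal_pair(self, rng, small_genome, two_baits):
        rows = []
        for i in range(20_000):
            a = int(rng.integers(0, small_genome["chr1"]))
            b = int(rng.integers(0, small_genome["chr2"]))
            rows.append((f"t{i}", "chr1", a, 60, "chr2", b, 60))
        idx = ContactIndex(pd.DataFrame(rows, columns=PAIR_COLUMNS), small_genome)
        bg = sample_background(
            GenomicInterval("chr1", 100_000, 105_000),
            GenomicInterval("chr2", 300_000, 305_000),
            idx, two_baits, small_genome, n=2000, seed=3, store_counts=True,
        )
        # expected: 20000 * (5k/1M) * (5k/0.8M) with both chroms possible hosts
        assert bg.mean > 0
        assert bg.counts.max() < 20


class TestCaptureRate:
    @pytest.mark.parametrize(
        "hit,total,expected",
        [(156, 157, 99.4), (753, 807, 93.3), (21, 22, 95.5),
         (18, 20, 90.0), (0, 10, 0.0), (40, 156, 25.6)],
    )
    def test_printed_worked_examples(self, hit, total, expected):
        assert capture_rate(hit, total) == expected

    def test_invalid(self):
        with pytest.raises(ValueError):
            capture_rate(1, 0)
        with pytest.raises(ValueError):
            capture_rate(5, 4)


class TestMergeSeBaits:
    def test_union_dedup_by_pair(self):
        baits = [
            BaitRegion("e1", GenomicInterval("c1", 100, 200), se_id="SE1"),
            BaitRegion("e2", GenomicInterval("c1", 400, 500), se_id="SE1"),
            BaitRegion("solo", GenomicInterval("c1", 900, 1000)),
        ]
        pets = pet_frame(
            [
                ("e1", "c1", 150, "c1", 5000, 4850.0, False, False, 0),
                ("e2", "c1", 450, "c1", 6000, 5550.0, False, False, 1),
                # the same source pair seen from both member baits
                ("e1", "c1", 150, "c1", 450, 300.0, False, True, 2),
                ("e2", "c1", 450, "c1", 150, 300.0, False, True, 2),
                ("solo", "c1", 950, "c1", 7000, 6050.0, False, False, 3),
            ]
        )
        merged_baits, merged_pets = merge_se_baits(baits, pets)
        by_id = {b.bait_id: b for b in merged_baits}
        assert set(by_id) == {"SE1", "solo"}
        assert by_id["SE1"].interval.start == 100
        assert by_id["SE1"].interval.end == 500
        se_pets = merged_pets[merged_pets["bait_id"] == "SE1"]
        assert len(se_pets) == 3  # pair 2 union-deduplicated
        assert sorted(se_pets["pair_index"]) == [0, 1, 2]


@pytest.fixture(scope="module")
def fitted(small_world):
    cfg, pairs, truth, baits = small_world
    from capture3c.pets import extract_pets

    pets, _ = extract_pets(pairs, baits)
    contacts = contacts_without_self_ligations(pairs, baits)
    model = InteractionModel(
        pets, baits, cfg.genome, ContactIndex(contacts, cfg.genome),
        CallConfig(seed=5),
    )
    return cfg, truth, model.fit()


class TestCallerOnPlantedLoops:
    """Seeded end-to-end checks on the shared small simulated world."""

    def test_planted_loops_called_significant(self, fitted):
        _, truth, res = fitted
        sig = res.significant
        for _, t in truth.iterrows():
            if t["n_extra"] == 0:
                continue
            hit = (
                (sig["bait_id"] == t["bait_id"])
                & (sig["chrom"] == t["chrom"])
                & (sig["start"] < t["end"]) & (t["start"] < sig["end"])
            ).any()
            assert hit, f"planted loop at {t['bait_id']}:{t['start']} missed"

    def test_calls_have_consistent_probabilities(self, fitted):
        _, _, res = fitted
        c = res.calls
        assert ((c["p_lt"] + c["p_ge"]).sub(1).abs() < 1e-9).all()
        assert (c["x"] >= 2).all()  # min_count honored
        assert (c.loc[c["significant"], "bf"] >= 20).all()

    def test_empirical_and_fitted_thresholds_agree_closely(self, small_world):
        # oracle-equivalence: calls from the NegBin fit vs the empirical
        # CDF of the same sampled counts may differ only near threshold
        cfg, pairs, truth, baits = small_world
        from capture3c.pets import extract_pets

        pets, _ = extract_pets(pairs, baits)
        contacts = contacts_without_self_ligations(pairs, baits)
        idx = ContactIndex(contacts, cfg.genome)
        fit_res = InteractionModel(
            pets, baits[:2], cfg.genome, idx, CallConfig(seed=5)
        ).fit(baits[:2])
        emp_res = InteractionModel(
            pets, baits[:2], cfg.genome, idx,
            CallConfig(seed=5, use_empirical=True),
        ).fit(baits[:2])
        merged = fit_res.calls.merge(
            emp_res.calls, on=["bait_id", "chrom", "start"], suffixes=("_fit", "_emp")
        )
        disagree = merged[merged["significant_fit"] != merged["significant_emp"]]
        # disagreements are rare borderline bins, never strong calls
        assert len(disagree) <= 0.02 * len(merged) + 2
        if len(disagree):
            assert (disagree["bf_fit"] < 20 * 50).all()

    def test_zero_pets_zero_calls(self, small_genome, two_baits):
        pets = pet_frame([])
        idx = ContactIndex(pd.DataFrame([], columns=PAIR_COLUMNS), small_genome)
        res = InteractionModel(
            pets, two_baits, small_genome, idx, CallConfig(seed=1)
        ).fit()
        assert len(res.calls) == 0
        assert len(res.significant) == 0

    def test_summary_mentions_capture_rate(self, fitted):
        _, _, res = fitted
        text = res.summary()
        assert "capture rate" in text
        assert "BF" in text
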