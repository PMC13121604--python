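"""Region RPKM, shuffle noise threshold, classification and barcode counts."""

import re

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rtswitch import (
    BinGrid,
    GenomeLayout,
    NascentTrack,
    NoiseThreshold,
    classify_regions,
    count_barcode_reads,
    domain_integration,
    label_regions_by_rt,
    noise_threshold,
    region_rpkm,
    transcription_change_test,
)
from rtswitch.transcription import RT_CLASSES, TX_CLASSES

from test_rt_profile import make_profile


def make_track(counts_by_key, bin_size=5_000):
    n = len(next(iter(counts_by_key.values())))
    layout = GenomeLayout(("c",), (bin_size * n,))
    track = NascentTrack(BinGrid(layout, bin_size))
    for (cond, rep), counts in counts_by_key.items():
        track.add(cond, rep, np.asarray(counts, dtype=float))
    return track


def regions_df(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


class TestRegionRPKM:
    def test_arithmetic(self):
        # 2000 reads over a 100 kb region, 20M library -> 1.0 RPKM
        counts = np.zeros(40)
        counts[:20] = 100.0  # 2000 reads in the first 100 kb
        track = make_track({("ESC", 1): counts})
        quant = region_rpkm(
            track, regions_df([("c", 0, 100_000)]), {("ESC", 1): 20_000_000}
        )
        assert quant.rpkm["ESC"][0, 0] == pytest.approx(1.0)

    def test_empty_region_is_zero(self):
        track = make_track({("ESC", 1): np.zeros(40)})
        quant = region_rpkm(track, regions_df([("c", 0, 100_000)]), {("ESC", 1): 1e6})
        assert quant.rpkm["ESC"][0, 0] == 0.0

    def test_partial_bin_overlap_apportioned(self):
        counts = np.zeros(4)
        counts[0] = 10.0
        track = make_track({("ESC", 1): counts})
        quant = region_rpkm(track, regions_df([("c", 0, 2_500)]), {("ESC", 1): 1e6})
        # half the first bin: 5 reads over 2.5 kb
        assert quant.rpkm["ESC"][0, 0] == pytest.approx(5 / 2.5)

    def test_rpkm_additivity_over_disjoint_equal_regions(self, rng):
        counts = rng.integers(0, 50, 200).astype(float)
        track = make_track({("ESC", 1): counts})
        libs = {("ESC", 1): 1e7}
        parts = regions_df([("c", 0, 250_000), ("c", 500_000, 750_000)])
        whole_rpkm = region_rpkm(track, parts, libs).rpkm["ESC"][:, 0]
        # mean of the two equal-length parts = RPKM of their union
        union_reads = track.grid.reads_in_interval(counts, "c", 0, 250_000) + \
            track.grid.reads_in_interval(counts, "c", 500_000, 750_000)
        union_rpkm = union_reads / (500.0 * 10)
        assert whole_rpkm.mean() == pytest.approx(union_rpkm)

    def test_zero_length_region_rejected(self):
        track = make_track({("ESC", 1): np.zeros(4)})
        with pytest.raises(ValueError):
            region_rpkm(track, regions_df([("c", 100, 100)]), {("ESC", 1): 1e6})


class TestNoiseThreshold:
    def layout(self):
        return GenomeLayout(("c",), (1_000_000,))

    def test_zero_background_gives_zero_threshold(self):
        track = make_track({("ESC", 1): np.zeros(200), ("NPC", 1): np.zeros(200)})
        thr = noise_threshold(
            track,
            regions_df([("c", 0, 50_000)]),
            regions_df([("c", 500_000, 600_000)]),
            self.layout(),
            n_shuffles=20,
            seed=0,
            library_sizes={("ESC", 1): 1e6, ("NPC", 1): 1e6},
        )
        assert thr.threshold == 0.0

    def test_nondecreasing_in_quantile(self, rng):
        track = make_track(
            {("ESC", 1): rng.poisson(5, 200).astype(float),
             ("NPC", 1): rng.poisson(5, 200).astype(float)}
        )
        args = (
            track,
            regions_df([("c", 0, 50_000), ("c", 100_000, 200_000)]),
            regions_df([("c", 800_000, 900_000)]),
            self.layout(),
        )
        thresholds = [
            noise_threshold(*args, n_shuffles=30, quantile=q, seed=4).threshold
            for q in (0.5, 0.9, 0.99)
        ]
        assert thresholds == sorted(thresholds)

    def test_negative_threshold_invalid(self):
        with pytest.raises(ValueError):
            NoiseThreshold(-0.1, 10, 0.99, np.empty(0))


class TestTranscriptionChange:
    @staticmethod
    def quant_from(rpkm1, rpkm2):
        from rtswitch import RegionQuant

        n = np.atleast_2d(rpkm1).shape[0]
        regions = regions_df([("c", i * 1000, (i + 1) * 1000) for i in range(n)])
        return RegionQuant(
            regions,
            {"ESC": np.atleast_2d(rpkm1), "NPC": np.atleast_2d(rpkm2)},
            ("ESC", "NPC"),
        )

    def test_identical_is_null(self):
        q = self.quant_from([[1.0, 2.0, 3.0]], [[1.0, 2.0, 3.0]])
        out = transcription_change_test(q)
        assert out.loc[0, "p"] if "p" in out else True
        assert out.loc[0, "p_tx"] == 1.0
        assert out.loc[0, "log2_fc"] == 0.0

    def test_matches_closed_form_paired_t(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 8))
            x = rng.uniform(0, 5, n)
            y = x + rng.normal(1.0, 0.3, n)
            out = transcription_change_test(self.quant_from([x], [y]))
            d = y - x
            t = d.mean() / (d.std(ddof=1) / np.sqrt(n))
            p = 2 * stats.t.sf(abs(t), n - 1)
            assert out.loc[0, "p_tx"] == pytest.approx(p, abs=1e-10)

    def test_pseudocount_fold_change(self):
        out = transcription_change_test(
            self.quant_from([[0.0, 0.0]], [[0.98, 1.0]]), pseudocount=0.01
        )
        assert out.loc[0, "log2_fc"] == pytest.approx(np.log2(100), rel=1e-6)


class TestClassification:
    @staticmethod
    def toy():
        regions = regions_df(
            [("c", i * 100_000, (i + 1) * 100_000) for i in range(6)]
        )
        regions["rt_class"] = [
            "advance", "advance", "advance", "delay", "no_change", "no_change",
        ]
        tx = regions[["chrom", "start", "end"]].copy()
        tx["rpkm_1"] = [0.0, 0.0, 0.01, 0.0, 5.0, 0.01]
        tx["rpkm_2"] = [5.0, 0.01, 0.5, 4.0, 1.0, 0.02]
        tx["log2_fc"] = [9.0, 0.0, 1.0, 8.0, -2.3, 1.0]
        tx["p_tx"] = [1e-6, 0.9, 0.2, 1e-5, 1e-4, 0.5]
        return regions, tx

    def test_hand_tabulation(self):
        regions, tx = self.toy()
        noise = NoiseThreshold(0.1, 10, 0.99, np.empty(0))
        out = classify_regions(regions, tx, noise, p_cut=0.01)
        t = out.table
        assert t.loc["advance", "up"] == 1
        assert t.loc["advance", "nc_below_noise"] == 1
        assert t.loc["advance", "nc_above_noise"] == 1
        assert t.loc["delay", "up"] == 1
        assert t.loc["no_change", "down"] == 1
        assert t.loc["no_change", "nc_below_noise"] == 1

    def test_partition_is_exhaustive_and_exclusive(self, rng):
        n = 200
        regions = regions_df([("c", i * 1000, (i + 1) * 1000) for i in range(n)])
        regions["rt_class"] = rng.choice(RT_CLASSES, n)
        tx = regions[["chrom", "start", "end"]].copy()
        tx["rpkm_1"] = rng.uniform(0, 2, n)
        tx["rpkm_2"] = rng.uniform(0, 2, n)
        tx["log2_fc"] = rng.normal(size=n)
        tx["p_tx"] = rng.uniform(1e-6, 1, n)
        out = classify_regions(regions, tx, NoiseThreshold(0.5, 1, 0.99, np.empty(0)))
        assert out.table.to_numpy().sum() == n
        assert len(out.labels) == n
        assert set(out.labels["tx_class"]) <= set(TX_CLASSES)

    def test_missing_statistic_named(self):
        regions, tx = self.toy()
        tx.loc[2, "p_tx"] = np.nan
        with pytest.raises(ValueError, match="200000-300000"):
            classify_regions(regions, tx, NoiseThreshold(0.1, 1, 0.99, np.empty(0)))

    def test_rt_labels_from_switch_overlap(self):
        regions = regions_df([("c", 0, 100_000), ("c", 200_000, 300_000)])
        switches = pd.DataFrame(
            {"chrom": ["c"], "start": [50_000], "end": [120_000],
             "direction": ["advance"]}
        )
        labels = label_regions_by_rt(regions, switches)
        assert labels.tolist() == ["advance", "no_change"]


class TestDomainIntegration:
    def test_domain_rpkm_matches_region_rpkm(self, rng):
        counts = {
            (c, r): rng.poisson(10, 200).astype(float)
            for c in ("ESC", "NPC") for r in (1, 2)
        }
        track = make_track(counts)
        profiles = {
            cond: [make_profile(rng.normal(size=10), bin_size=100_000) for _ in range(2)]
            for cond in ("ESC", "NPC")
        }
        domains = regions_df([("c", 0, 200_000), ("c", 500_000, 800_000)])
        out = domain_integration(domains, profiles, track)
        quant = region_rpkm(track, domains)
        assert np.allclose(out["rpkm_2"], quant.rpkm["NPC"].mean(axis=1))
        assert not out["excluded"].any()

    def test_identical_conditions_null_rt(self, rng):
        counts = {(c, r): rng.poisson(10, 200).astype(float)
                  for c in ("ESC", "NPC") for r in (1, 2)}
        track = make_track(counts)
        prof = [make_profile(rng.normal(size=10), bin_size=100_000) for _ in range(2)]
        domains = regions_df([("c", 0, 500_000)])
        out = domain_integration(domains, {"ESC": prof, "NPC": prof}, track)
        assert out.loc[0, "delta_rt"] == 0.0
        assert out.loc[0, "p_rt"] == 1.0


class TestBarcodes:
    BC = "ACGTACGTACGTACGT"

    def write_fastq(self, path, seqs):
        with open(path, "w") as fh:
            for i, s in enumerate(seqs):
                fh.write(f"@r{i}\n{s}\n+\n{'I' * len(s)}\n")

    def test_rpm_arithmetic_with_declared_total(self, tmp_path, rng):
        reads = ["".join(rng.choice(list("ACGT"), 50)) for _ in range(200)]
        for i in range(50):
            reads[i] = reads[i][:10] + self.BC + reads[i][10 + 16:]
        path = tmp_path / "r.fastq"
        self.write_fastq(path, reads)
        out = count_barcode_reads(path, [self.BC], total_reads=1_000_000)
        matches = sum(1 for s in reads if self.BC in s)
        assert out.loc[0, "count"] == matches
        assert out.loc[0, "rpm"] == pytest.approx(matches / 1_000_000 * 1e6)

    def test_double_occurrence_counts_once_vs_regex_oracle(self, tmp_path, rng):
        reads = ["".join(rng.choice(list("ACGT"), 60)) for _ in range(100)]
        reads[0] = self.BC + "TTTT" + self.BC  # double occurrence
        reads[1] = "A" * 20 + self.BC + "A" * 10
        path = tmp_path / "r.fastq"
        self.write_fastq(path, reads)
        out = count_barcode_reads(path, [self.BC])
        oracle = sum(1 for s in reads if re.search(re.escape(self.BC), s))
        assert out.loc[0, "count"] == oracle

    def test_absent_barcode_zero_rpm(self, tmp_path):
        path = tmp_path / "r.fastq"
        self.write_fastq(path, ["ACGT" * 20])
        out = count_barcode_reads(path, ["T" * 16])
        assert out.loc[0, "rpm"] == 0.0

    @pytest.mark.parametrize("bad", ["ACGT", "N" * 16, "acgtacgtacgtacgt"])
    def test_invalid_barcodes_rejected(self, tmp_path, bad):
        path = tmp_path / "r.fastq"
        self.write_fastq(path, ["ACGT" * 20])
        with pytest.raises(ValueError):
            count_barcode_reads(path, [bad])
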