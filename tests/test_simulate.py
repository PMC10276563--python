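"""Synthetic-data generator: determinism, invariants, calibrations."""

import datetime as dt
import itertools

import numpy as np
import pytest

from planktax.pcr import builtin_pair, extract_amplicons
from planktax.qc import run_qc
from planktax.simulate import (CommunityScenario, SimParams,
                               generate_reference_databases,
                               generate_scenario, generate_taxon_pool,
                               simulate_reads, sst_model, taxon_amplicons,
                               write_fastq)
from planktax.compare import DEFAULT_SEASON_MAP


class TestTaxonPool:
    def test_zero_species_rejected(self):
        with pytest.raises(ValueError):
            generate_taxon_pool(0, 1)

    def test_single_taxon_yields_one_amplicon_under_18s_pair(self):
        pool = generate_taxon_pool(1, 1, frac_warm=0.0,
                                   params=SimParams(seed=7), markers=("18S",))
        hits = extract_amplicons("t", pool[0].marker_seqs["18S"],
                                 builtin_pair("18S"))
        assert len(hits) == 1

    def test_seeded_determinism_is_byte_identical(self, tmp_path):
        outs = []
        for run in range(2):
            pool = generate_taxon_pool(24, 8, params=SimParams(seed=7))
            fasta = "".join(f">{t.taxon_id}\n{t.marker_seqs['18S']}\n"
                            f"{t.marker_seqs['28S']}\n" for t in pool)
            outs.append(fasta.encode())
        assert outs[0] == outs[1]

    def test_every_marker_recovers_exactly_one_amplicon(self, small_pool):
        for marker in ("18S", "28S"):
            amps = taxon_amplicons(small_pool, marker)
            assert len(amps) == len(small_pool)
            assert all(len(a) < 500 for a in amps.values())

    def test_within_genus_divergence_matches_substitution_model(self):
        """Mean pairwise amplicon identity within genera tracks the
        two-lineage substitution expectation, checked against a brute-force
        per-position comparison."""
        r = 0.02
        params = SimParams(seed=7, divergence_rate_within_genus=r)
        pool = generate_taxon_pool(24, 8, params=params, markers=("18S",))
        amps = taxon_amplicons(pool, "18S")
        idents = []
        for a, b in itertools.combinations(pool, 2):
            if a.genus != b.genus:
                continue
            x, y = amps[a.taxon_id], amps[b.taxon_id]
            assert len(x) == len(y)
            diffs = sum(c != d for c, d in zip(x, y))
            assert diffs >= 1  # species are distinguishable
            idents.append(1 - diffs / len(x))
        core_frac = 400 / len(x)
        assert np.mean(idents) == pytest.approx(1 - 2 * r * core_frac,
                                                abs=0.01)

    def test_registration_and_warmth_assignment(self, small_pool):
        reg = {k: sum(t.registration == k for t in small_pool)
               for k in ("species_in_old", "genus_only_in_old", "new_only",
                         "absent")}
        assert reg == {"species_in_old": 4, "genus_only_in_old": 2,
                       "new_only": 4, "absent": 2}
        warm = [t for t in small_pool if t.thermal_affinity == "warm"]
        assert len(warm) == 3
        assert all(t.registration in ("new_only", "absent") for t in warm)


class TestSstModel:
    def test_zero_noise_is_pure_symmetric_sinusoid(self):
        p = SimParams(sst_noise_sd=0.0)
        days = [dt.date(2013, 1, 1) + dt.timedelta(days=i) for i in range(365)]
        v = np.array([sst_model(d, p) for d in days])
        assert v.max() - 8.7 == pytest.approx(8.7 - v.min(), abs=0.01)
        assert v.max() == pytest.approx(8.7 + 10.3, abs=0.01)

    def test_seasonal_means_near_observed_climatology(self):
        p = SimParams(seed=0)
        dates = [dt.date(2012, 4, 3) + dt.timedelta(weeks=w)
                 for w in range(208)]
        groups = {}
        for d in dates:
            groups.setdefault(DEFAULT_SEASON_MAP[d.month], []).append(
                sst_model(d, p))
        targets = {"spring": 3.8, "summer": 16.4, "autumn": 13.8,
                   "winter": 0.8}
        for season, target in targets.items():
            assert abs(np.mean(groups[season]) - target) < 2.0

    def test_noise_extends_range_beyond_sinusoid(self):
        dates = [dt.date(2012, 4, 3) + dt.timedelta(weeks=w)
                 for w in range(208)]
        noisy = np.array([sst_model(d, SimParams(seed=0)) for d in dates])
        quiet = np.array([sst_model(d, SimParams(sst_noise_sd=0.0))
                          for d in dates])
        # observed coastal range is wider than the seasonal cycle alone
        assert noisy.min() <= -1.7 < quiet.min()
        assert noisy.max() >= 22.2 > quiet.max()

    def test_deterministic_per_date_and_seed(self):
        d = dt.date(2014, 8, 1)
        assert sst_model(d, SimParams(seed=5)) == sst_model(d, SimParams(seed=5))
        assert sst_model(d, SimParams(seed=5)) != sst_model(d, SimParams(seed=6))


class TestScenario:
    def test_warm_taxa_confined_to_warm_window(self, small_pool):
        params = SimParams(seed=7)
        scen = generate_scenario(small_pool, years=2, params=params)
        warm = np.array([t.thermal_affinity == "warm" for t in small_pool])
        for s in scen.samples:
            in_window = (s.date.month in params.warm_months
                         and s.sst_celsius > params.warm_sst_threshold)
            if not in_window:
                assert s.abundance[warm].sum() == 0
            assert (s.abundance >= 0).all()
            assert s.abundance.sum() > 0


class TestSimulateReads:
    def test_error_free_single_taxon_reads_merge_to_amplicon(self):
        params = SimParams(seed=3, depth_per_sample=100,
                           substitution_error_rate=0.0, chimera_rate=0.0)
        pool = generate_taxon_pool(1, 1, frac_warm=0.0, params=params,
                                   markers=("18S",))
        scen = generate_scenario(pool, years=1, params=params)
        scen.samples = scen.samples[:1]
        reads, truth = simulate_reads(scen, "18S", params)
        amp = taxon_amplicons(pool, "18S")[pool[0].taxon_id]
        r1s, r2s = next(iter(reads.values()))
        merged, counts = run_qc(list(zip(r1s, r2s)))
        assert counts.merged == 100
        assert all(m.bases == amp for m in merged)

    def test_chimera_count_within_binomial_bounds(self):
        params = SimParams(seed=11, depth_per_sample=1000, chimera_rate=0.1,
                           substitution_error_rate=0.0)
        pool = generate_taxon_pool(4, 2, frac_warm=0.0, params=params,
                                   markers=("18S",))
        scen = generate_scenario(pool, years=1, params=params)
        scen.samples = scen.samples[:1]
        reads, truth = simulate_reads(scen, "18S", params)
        n_chim = truth.loc[truth.registration == "chimera", "abundance"].sum()
        sd = np.sqrt(1000 * 0.1 * 0.9)
        assert abs(n_chim - 100) <= 3 * sd

    def test_abundance_ratio_within_binomial_bounds(self):
        params = SimParams(seed=13, depth_per_sample=1000, chimera_rate=0.0,
                           substitution_error_rate=0.0)
        pool = generate_taxon_pool(2, 2, frac_warm=0.0, params=params,
                                   markers=("18S",))
        scen = generate_scenario(pool, years=1, params=params)
        s = scen.samples[0]
        s.abundance = np.array([9.0, 1.0])
        scen.samples = [s]
        reads, truth = simulate_reads(scen, "18S", params)
        counts = truth.set_index("taxon_id")["abundance"]
        sd9 = np.sqrt(1000 * 0.9 * 0.1)
        assert abs(counts["T001"] - 900) <= 3 * sd9
        assert abs(counts["T002"] - 100) <= 3 * sd9

    def test_every_read_maps_to_a_truth_entry(self, small_pool):
        params = SimParams(seed=7, depth_per_sample=60)
        scen = generate_scenario(small_pool, years=1, params=params)
        scen.samples = scen.samples[:3]
        reads, truth = simulate_reads(scen, "18S", params)
        keyed = {(r.taxon_id, r.sample_id): r.abundance
                 for r in truth.itertuples()}
        for sample_id, (r1s, _r2s) in reads.items():
            seen = {}
            for r in r1s:
                s, taxon, _serial = r.read_id.split(":")
                assert s == sample_id
                seen[(taxon, s)] = seen.get((taxon, s), 0) + 1
            assert seen == {k: v for k, v in keyed.items()
                            if k[1] == sample_id}

    def test_fastq_output_is_deterministic(self, tmp_path, small_pool):
        params = SimParams(seed=7, depth_per_sample=30)
        blobs = []
        for run in range(2):
            scen = generate_scenario(small_pool, years=1, params=params)
            scen.samples = scen.samples[:2]
            reads, _ = simulate_reads(scen, "18S", params)
            path = tmp_path / f"run{run}.fastq"
            write_fastq([r for r1s, _ in reads.values() for r in r1s], path)
            blobs.append(path.read_bytes())
        assert blobs[0] == blobs[1]

    def test_empty_scenario_rejected(self, small_pool):
        params = SimParams(seed=7)
        with pytest.raises(ValueError):
            simulate_reads(CommunityScenario([], small_pool, 7), "18S", params)
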