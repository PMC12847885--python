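"""End-to-end analysis: joins, strata, headline calls, determinism."""

import dataclasses

import numpy as np
import pytest

import ribostress as rs


def _flat_transcripts(n=60):
    """Transcripts with identical architecture across a p-value spread."""
    recs, de = [], []
    for i in range(n):
        tid = f"T{i:03d}"
        recs.append(rs.TranscriptRecord(tid, f"G{i:03d}", "+",
                                        exons=[(0, 100), (200, 300)],
                                        cds=[(50, 100), (200, 250)]))
        de.append(rs.DERecord(tid, 0.5, (i + 0.5) / n))
    return de, recs


class TestRunConfig:
    def test_defaults_are_the_study_thresholds(self):
        cfg = rs.RunConfig()
        assert (cfg.alpha, cfg.k_deciles, cfg.slice_frac_small, cfg.slice_frac_fc) == \
            (0.05, 10, 0.025, 0.25)

    @pytest.mark.parametrize("kwargs", [
        {"alpha": 1.0}, {"alpha": 0.0}, {"k_deciles": 0},
        {"slice_frac_small": 0.7}, {"test_method": "anova"},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(rs.ConfigError):
            rs.RunConfig(**kwargs)


class TestTranscriptAnalysis:
    def test_identical_architecture_yields_no_directions(self):
        de, recs = _flat_transcripts()
        block = rs.run_transcript_analysis(de, recs, rs.RunConfig(k_deciles=5))
        for comp in block.decile_comparisons + block.slice_comparisons:
            assert comp.direction == "none"
        assert not any(call["flag"] for call in block.headline.values())

    def test_strata_disjoint_and_exhaustive(self, small_sim):
        tsim, _, cfg = small_sim
        block = rs.run_transcript_analysis(tsim.de_records, tsim.transcripts, rs.RunConfig())
        assert block.stratum_sizes["significant"] + block.stratum_sizes["nonsignificant"] \
            == block.n_joined

    def test_unjoined_records_are_counted(self, small_sim):
        tsim, _, _ = small_sim
        de = tsim.de_records + [rs.DERecord("ghost", 0.0, 0.01)]
        block = rs.run_transcript_analysis(de, tsim.transcripts, rs.RunConfig())
        assert block.n_unjoined == 1

    def test_gene_level_fallback_uses_longest_cds_representative(self):
        recs = [
            rs.TranscriptRecord("tA1", "gA", "+", exons=[(0, 300)], cds=[(50, 100)]),
            rs.TranscriptRecord("tA2", "gA", "+", exons=[(0, 900)], cds=[(50, 700)]),
            rs.TranscriptRecord("tB1", "gB", "+", exons=[(0, 500)], cds=[(100, 200)]),
        ]
        de = [rs.DERecord("gA", 1.0, 0.01), rs.DERecord("gB", 1.0, 0.02)]
        block = rs.run_transcript_analysis(de, recs, rs.RunConfig(k_deciles=2))
        assert block.join_level == "gene" and block.n_joined == 2
        # the representative of gA is tA2 (longest CDS): exon_len 900
        sig = block.decile_summary.query("feature == 'exon_len' and stratum == 'significant'")
        assert sorted(sig["median"].astype(float)) == [500.0, 900.0]

    def test_zero_join_raises(self):
        de = [rs.DERecord("nope", 0.0, 0.01), rs.DERecord("nada", 0.0, 0.2)]
        recs = [rs.TranscriptRecord("t1", "g1", "+", exons=[(0, 100)])]
        with pytest.raises(rs.JoinError):
            rs.run_transcript_analysis(de, recs, rs.RunConfig())

    def test_no_cds_transcripts_kept_for_exon_dropped_for_utr(self):
        de, recs = _flat_transcripts(40)
        naked = [rs.TranscriptRecord(f"N{i}", f"NG{i}", "+", exons=[(0, 500)])
                 for i in range(10)]
        de += [rs.DERecord(f"N{i}", 0.1, 0.01 + i * 0.001) for i in range(10)]
        block = rs.run_transcript_analysis(de + [], recs + naked, rs.RunConfig(k_deciles=2))
        assert block.n_no_cds == 10
        sig = block.decile_summary.query("stratum == 'significant'")
        exon_n = sig.query("feature == 'exon_len'").n_values.sum()
        utr_n = sig.query("feature == 'utr5_len'").n_values.sum()
        assert exon_n == utr_n + 10  # naked transcripts counted for exon only


class TestProteinAnalysis:
    def test_identical_sequences_yield_no_directions(self):
        prots = [rs.ProteinRecord(f"P{i}", "MIVK" * 10) for i in range(40)]
        # 20 significant / 20 non-significant records over identical sequences
        de = [rs.DERecord(f"P{i}", (i - 20) / 5, (i + 0.5) / 40 * 0.1 if i < 20 else 0.5 + i / 100)
              for i in range(40)]
        block = rs.run_protein_analysis(de, prots, rs.RunConfig())
        for comp in block.group_comparisons + block.fraction_comparisons + block.slice_comparisons:
            assert comp.direction == "none"
            assert comp.pvalue == pytest.approx(1.0)

    def test_fraction_family_is_bh_adjusted(self, small_sim):
        _, psim, _ = small_sim
        block = rs.run_protein_analysis(psim.de_records, psim.proteins, rs.RunConfig())
        assert len(block.fraction_comparisons) == 20
        for comp in block.fraction_comparisons:
            assert comp.adjusted_pvalue is not None
            assert comp.adjusted_pvalue >= comp.pvalue - 1e-12

    def test_undefined_ile_to_val_counted_and_excluded(self):
        prots = [rs.ProteinRecord(f"P{i}", "MIIK" * 10) for i in range(4)]  # no Val
        prots += [rs.ProteinRecord(f"Q{i}", "MIVK" * 10) for i in range(4)]
        de = [rs.DERecord(p.protein_id, 1.0 + i, 0.01) for i, p in enumerate(prots)]
        de += [rs.DERecord("zz", 0.0, 0.9)]
        prots.append(rs.ProteinRecord("zz", "MIVK" * 5))
        block = rs.run_protein_analysis(de, prots, rs.RunConfig())
        assert block.ile_to_val["significant"]["n_undefined"] == 4

    def test_slice_sizes_follow_rounding_rule(self, small_sim):
        _, psim, cfg = small_sim
        block = rs.run_protein_analysis(psim.de_records, psim.proteins, rs.RunConfig())
        assert block.slice_size == rs.slice_size(block.n_sig, 0.25)


class TestModelResults:
    def test_fit_recovers_planted_truth_at_defaults(self):
        sim_cfg = rs.SimConfig(seed=29)
        tsim = rs.simulate_transcripts(sim_cfg)
        psim = rs.simulate_proteins(sim_cfg)
        res = rs.RibosomalStressModel(
            de_transcripts=tsim.de_records, transcripts=tsim.transcripts,
            de_proteins=psim.de_records, proteins=psim.proteins).fit()
        calls = res.headline_calls
        for feat, exp in {**tsim.truth["expected_calls"],
                          **psim.truth["expected_calls"]}.items():
            assert calls[feat]["flag"] == exp["flag"], feat
            if exp["flag"]:
                assert calls[feat]["direction"] == exp["direction"], feat

    def test_config_echo_reproduces_thresholds_exactly(self, small_sim):
        tsim, psim, _ = small_sim
        res = rs.RibosomalStressModel(
            de_transcripts=tsim.de_records, transcripts=tsim.transcripts).fit()
        echo = res.summary_dict()["config"]
        assert echo["alpha"] == 0.05 and echo["k_deciles"] == 10
        assert echo["slice_frac_small"] == 0.025 and echo["slice_frac_fc"] == 0.25

    def test_refit_is_deterministic(self, small_sim):
        tsim, psim, _ = small_sim
        model = rs.RibosomalStressModel(
            de_transcripts=tsim.de_records, transcripts=tsim.transcripts,
            de_proteins=psim.de_records, proteins=psim.proteins)
        assert model.fit().summary_dict() == model.fit().summary_dict()

    def test_summary_text_mentions_group_sizes(self, small_sim):
        tsim, psim, _ = small_sim
        res = rs.RibosomalStressModel(
            de_proteins=psim.de_records, proteins=psim.proteins).fit()
        text = res.summary()
        assert "Headline calls" in text and "ile_fraction" in text

    def test_mismatched_inputs_rejected(self, small_sim):
        tsim, _, _ = small_sim
        with pytest.raises(rs.ConfigError):
            rs.RibosomalStressModel(de_transcripts=tsim.de_records)
        with pytest.raises(rs.ConfigError):
            rs.RibosomalStressModel()


class TestMonotoneSensitivity:
    def test_exon_detection_rate_increases_with_effect(self):
        """Over a 3-point effect grid the decile-trend rejection rate for
        exon length never decreases (scaled-down problem: 500 significant
        transcripts, 200 replicates per grid point)."""
        rates = []
        for effect in (0.0, 0.25, 0.5):
            hits = 0
            reps = 200
            for seed in range(reps):
                cfg = rs.SimConfig(n_transcripts=500, frac_significant=0.5,
                                   exon_effect=effect, seed=100_000 + seed)
                tsim = rs.simulate_transcripts(cfg)
                block = rs.run_transcript_analysis(
                    tsim.de_records, tsim.transcripts, rs.RunConfig())
                hits += block.headline["exon_len"]["flag"]
            rates.append(hits / reps)
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[2] > 0.8  # strong effect is actually detectable
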