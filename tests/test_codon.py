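"""Codon machinery: shuffles, mutable positions, GeRM codon ratios,
conservation normalization, CDS recoding."""

import itertools

import numpy as np
import pandas as pd
import pytest

from germ import (
    GermParams,
    ShuffleConfig,
    TranscriptModel,
    enumerate_mutable_positions,
    germ_codon_ratio,
    mean_shuffled_germ,
    normalize_conservation,
    recode_cds,
    shuffle_codons,
    simulate_conservation,
)
from germ.codon import (
    _codons_checked,
    _synonymous_single_substitutions,
    codon_ratio_records,
    count_ag_only_kmers,
)
from germ.core import score_transcript
from germ.io import ConservationTrack
from germ.sequence import CODON_TABLE, SYNONYMOUS, gc_content, split_codons, translate

from conftest import random_seq


def random_cds(rng, n_codons):
    codons = sorted(CODON_TABLE)
    return "".join(rng.choice(codons, size=n_codons))


class TestShuffleCodons:
    def test_codon_counts_preserved_within_transcript(self):
        out = shuffle_codons({"t": "AAAAAGAAA"}, ShuffleConfig(seed=1))
        codons = split_codons(out["t"])
        assert sorted(codons) == ["AAA", "AAA", "AAG"]

    def test_single_codon_per_amino_acid_is_identity(self):
        cds = "ATGTGGATG"  # Met Trp Met: no synonymous freedom
        out = shuffle_codons({"t": cds}, ShuffleConfig(seed=5))
        assert out["t"] == cds

    def test_protein_preserved_for_random_cds_both_scopes(self, rng):
        cds_set = {f"t{i}": random_cds(rng, 60) for i in range(20)}
        for scope in ("within_transcript", "transcriptome_wide"):
            out = shuffle_codons(cds_set, ShuffleConfig(scope=scope, seed=2))
            for tid in cds_set:
                assert translate(out[tid]) == translate(cds_set[tid])

    def test_transcriptome_scope_moves_codons_between_transcripts(self):
        cds_set = {"a": "AAA" * 10, "b": "AAG" * 10}
        out = shuffle_codons(cds_set, ShuffleConfig(scope="transcriptome_wide", seed=0))
        # pooled Lys codons redistribute across both transcripts
        assert "AAG" in split_codons(out["a"]) or "AAA" in split_codons(out["b"])
        pooled = sorted(split_codons(out["a"]) + split_codons(out["b"]))
        assert pooled == ["AAA"] * 10 + ["AAG"] * 10

    def test_internal_stop_is_hard_error(self):
        with pytest.raises(ValueError, match="stop"):
            shuffle_codons({"t": "AAATAAAAA"}, ShuffleConfig(seed=0))

    def test_seed_reproducible(self, rng):
        cds_set = {f"t{i}": random_cds(rng, 50) for i in range(5)}
        a = shuffle_codons(cds_set, ShuffleConfig(seed=11))
        b = shuffle_codons(cds_set, ShuffleConfig(seed=11))
        assert a == b


class TestMeanShuffledGerm:
    def test_identity_cds_mean_equals_native(self, params):
        cds = "ATGTGGATGTGG" * 20  # Met/Trp only: shuffle is identity
        out = mean_shuffled_germ({"t": cds}, ShuffleConfig(n_shuffles=3, seed=0), params)
        assert np.allclose(out["t"], score_transcript(cds, params))

    def test_bitwise_reproducible_across_runs(self, params, rng):
        cds_set = {"t": random_cds(rng, 80)}
        cfg = ShuffleConfig(n_shuffles=1, seed=42)
        a = mean_shuffled_germ(cds_set, cfg, params)
        b = mean_shuffled_germ(cds_set, cfg, params)
        assert np.array_equal(a["t"], b["t"])

    def test_planted_ga_region_native_exceeds_shuffle_mean(self, params):
        """Codon-biased multivalent regions lose score under the synonymous
        shuffle null (the direction of the planted effect)."""
        from germ.simulate import _planted_codons

        rng = np.random.default_rng(8)
        wins = 0
        for i in range(20):
            background = random_cds(rng, 150)
            planted = "".join(_planted_codons("GA", 100, 0.9, rng))
            cds = background[: 75 * 3] + planted + background[75 * 3 :]
            null = mean_shuffled_germ(
                {"t": cds}, ShuffleConfig(n_shuffles=10, seed=100 + i), params
            )["t"]
            native = score_transcript(cds, params)
            s, e = 75 * 3, 75 * 3 + 300
            wins += native[s:e].mean() > null[s:e].mean()
        assert wins >= 19


class TestMutablePositions:
    def test_met_codon_has_no_mutable_positions(self):
        assert enumerate_mutable_positions("ATG") == []

    def test_cga_arginine_has_two_mutable_positions(self):
        out = enumerate_mutable_positions("CGA")
        assert (0, 0, ["A"]) in out  # CGA -> AGA
        third = [x for x in out if x[1] == 2]
        assert third == [(0, 2, ["C", "G", "T"])]

    def test_ggg_glycine_third_position_only(self):
        assert enumerate_mutable_positions("GGG") == [(0, 2, ["A", "C", "T"])]

    def test_agrees_with_exhaustive_genetic_code_scan(self):
        """Every sense codon: positions listed iff a synonymous single-base
        substitution exists, enumerated directly from the code table."""
        for codon in sorted(CODON_TABLE):
            expected = {}
            for off, base in itertools.product(range(3), "ACGT"):
                if base == codon[off]:
                    continue
                var = codon[:off] + base + codon[off + 1 :]
                if CODON_TABLE.get(var) == CODON_TABLE[codon]:
                    expected.setdefault(off, []).append(base)
            got = {
                off: alts for _, off, alts in enumerate_mutable_positions(codon)
            }
            assert got == expected, codon

    def test_leucine_arginine_first_positions_included(self):
        firsts = {
            codon: dict((off, a) for _, off, a in enumerate_mutable_positions(codon)).get(0)
            for codon in ("CTA", "CTG", "TTA", "TTG", "CGA", "CGG", "AGA", "AGG")
        }
        assert all(v is not None for v in firsts.values())


class TestGermCodonRatio:
    def test_non_mutable_position_is_hard_error(self, params):
        with pytest.raises(ValueError):
            germ_codon_ratio("GGATTTGGA" * 20, 0, 0, 1, params)  # middle base

    def test_symmetric_degenerate_context_gives_ratio_one(self, params):
        """A context where native and every variant yield identical (here:
        empty) scoreable k-mer sets has ratio exactly 1."""
        rec = germ_codon_ratio("AAA", 0, 0, 2, params)  # lone Lys codon
        assert rec.native_max_germ == 0.0
        assert rec.ratio == 1.0

    def test_native_homopolymer_beats_variants(self, params):
        cds = "GGG" * 41
        rec = germ_codon_ratio(cds, 0, 20, 2, params)  # central GGG third base
        assert rec.ratio > 1

    def test_aga_in_gaa_repeat_supports_multivalency(self, params):
        """An AGA arginine codon inside a (GAA)n glutamate repeat matches the
        GA-rich neighbourhood better than its CG-containing alternatives."""
        cds = "GAA" * 30 + "AGA" + "GAA" * 30
        rec = germ_codon_ratio(cds, 0, 30, 0, params)  # first base of AGA
        assert rec.native_codon == "AGA"
        assert rec.ratio > 1

    def test_matches_full_transcript_rescore(self, params, rng):
        """Local-window scoring equals rebuilding and rescoring the whole
        mutated transcript (exactly)."""
        for _ in range(3):
            cds = random_cds(rng, 60)
            utr5, utr3 = random_seq(rng, 40), random_seq(rng, 40)
            model = TranscriptModel("t", "g", utr5 + cds + utr3, [len(utr5 + cds + utr3)],
                                    len(utr5), len(utr5) + len(cds))
            recs = codon_ratio_records(model, params)
            seq = model.spliced_sequence
            full = score_transcript(seq, params)
            for rec in recs.sample(n=min(20, len(recs)), random_state=1).itertuples():
                q = model.cds_start + 3 * rec.codon_index + rec.mutable_offset
                starts = range(max(0, q - 4), min(len(full), q + 1))
                assert max(full[p] for p in starts) == pytest.approx(
                    rec.native_max_germ, abs=1e-12
                )
                codon = seq[model.cds_start + 3 * rec.codon_index :][:3]
                alts = _synonymous_single_substitutions(codon)[rec.mutable_offset]
                maxima = []
                for b in alts:
                    mutated = seq[:q] + b + seq[q + 1 :]
                    remut = score_transcript(mutated, params)
                    maxima.append(max(remut[p] for p in starts))
                assert np.mean(maxima) == pytest.approx(
                    rec.mutant_mean_max_germ, abs=1e-12
                )

    def test_edge_positions_not_excluded(self, params):
        """Mutable positions near the transcript edge still produce records
        (out-of-bounds neighbour terms are 0 for native and variants alike)."""
        cds = "AAAGAAAGA" * 5  # K E K E ... all with mutable third positions
        model = TranscriptModel("t", "g", cds, [len(cds)], 0, len(cds))
        recs = codon_ratio_records(model, params)
        assert (recs.codon_index == 0).any()
        assert (recs.codon_index == len(cds) // 3 - 1).any()


class TestNormalizeConservation:
    def _records(self, model, params):
        return codon_ratio_records(model, params)

    def test_constant_track_normalizes_to_zero(self, params, rng):
        cds = random_cds(rng, 80)
        model = TranscriptModel("t", "g", cds, [len(cds)], 0, len(cds))
        recs = self._records(model, params)
        cons = {"t": ConservationTrack("t", np.full(model.length, 3.7))}
        df, summary = normalize_conservation(recs, cons, {"t": model})
        assert np.allclose(df["norm_conservation"], 0.0)
        assert np.allclose(summary["mean"], 0.0)

    def test_bins_have_equal_per_codon_proportions(self, params, rng):
        cds = random_cds(rng, 200)
        model = TranscriptModel("t", "g", cds, [len(cds)], 0, len(cds))
        recs = self._records(model, params)
        cons = {"t": ConservationTrack("t", rng.normal(size=model.length))}
        df, _ = normalize_conservation(recs, cons, {"t": model}, n_bins=4)
        for _, sub in df.groupby(["native_codon", "mutable_offset"]):
            counts = sub["bin"].value_counts()
            assert counts.max() - counts.min() <= 1

    def test_missing_conservation_drops_records(self, params, rng):
        cds = random_cds(rng, 60)
        model = TranscriptModel("t", "g", cds, [len(cds)], 0, len(cds))
        recs = self._records(model, params)
        values = rng.normal(size=model.length)
        values[::7] = np.nan
        cons = {"t": ConservationTrack("t", values)}
        df, _ = normalize_conservation(recs, cons, {"t": model})
        assert len(df) < len(recs)
        assert df["norm_conservation"].notna().all()

    def test_planted_delta_monotone_and_recovered(self, params, rng):
        """conservation = base + delta * 1[ratio > 1] + noise: bin means rise
        monotonically and the top-bottom contrast recovers delta."""
        models, recs = {}, []
        for i in range(4):
            cds = random_cds(rng, 150)
            m = TranscriptModel(f"t{i}", f"g{i}", cds, [len(cds)], 0, len(cds))
            models[f"t{i}"] = m
            recs.append(codon_ratio_records(m, params))
        records = pd.concat(recs, ignore_index=True)
        cons = simulate_conservation(models, records, delta=1.0, noise_sd=0.0, seed=4)
        df, summary = normalize_conservation(records, cons, models)
        means = summary.sort_values("bin")["mean"].to_numpy()
        assert means[-1] > means[0]
        est = (
            df.loc[df.ratio > 1, "norm_conservation"].mean()
            - df.loc[df.ratio <= 1, "norm_conservation"].mean()
        )
        assert est > 0.5  # attenuated by per-type median centring, sign robust


class TestRecodeCds:
    TOY = "AAAGAAAGAAGAGAA"  # K E K R E: AG-rich natively

    def test_protein_and_gc_always_preserved(self, rng):
        for _ in range(5):
            cds = random_cds(rng, 30)
            out = recode_cds(cds, "minimize", seed=3, n_restarts=3)
            assert translate(out) == translate(cds)
            assert abs(gc_content(out) - gc_content(cds)) <= 0.02 + 1e-12

    def test_minimize_reduces_but_lysine_floor_remains(self):
        # R/S codons admit GC-compensating swaps (AGA->CGA with AGC->AGT),
        # so the A/G-only count can drop under the GC constraint
        toy = "AGA" + "AGC" + "GAA" + "AAA" + "AGA" + "AGT"
        out = recode_cds(toy, "minimize", seed=0)
        assert count_ag_only_kmers(out) < count_ag_only_kmers(toy)
        # K/E-only CDSs are A/G-only under every synonymous choice: a floor
        # remains and minimization cannot go below it
        lys_glu = "AAAGAAAAAGAAGAA"
        floor = recode_cds(lys_glu, "minimize", seed=0)
        assert count_ag_only_kmers(floor) == count_ag_only_kmers(lys_glu) > 0

    def test_max_native_min_ordering(self):
        mx = count_ag_only_kmers(recode_cds(self.TOY, "maximize", seed=0))
        mn = count_ag_only_kmers(recode_cds(self.TOY, "minimize", seed=0))
        assert mx >= count_ag_only_kmers(self.TOY) >= mn

    def test_protected_spans_byte_identical(self):
        cds = "AAAGAAAGAAGAGAAAGAAAA"
        out = recode_cds(cds, "minimize", protected_spans=[(0, 9)], seed=0)
        assert out[:9] == cds[:9]
        assert translate(out) == translate(cds)

    def test_matches_exhaustive_on_toys(self, rng):
        def exhaustive(cds, objective, tol=0.02):
            codons = _codons_checked(cds)
            gc0 = gc_content(cds)
            best = None
            for combo in itertools.product(
                *[sorted(SYNONYMOUS[CODON_TABLE[c]]) for c in codons]
            ):
                seq = "".join(combo)
                if abs(gc_content(seq) - gc0) > tol + 1e-12:
                    continue
                v = count_ag_only_kmers(seq)
                v = -v if objective == "maximize" else v
                if best is None or v < best:
                    best = v
            return best

        aas = list("KERGALSP")
        for trial in range(3):
            cds = "".join(
                rng.choice(sorted(SYNONYMOUS[a]))
                for a in rng.choice(aas, int(rng.integers(5, 8)))
            )
            for obj in ("minimize", "maximize"):
                got = count_ag_only_kmers(recode_cds(cds, obj, seed=1))
                got = -got if obj == "maximize" else got
                assert got == exhaustive(cds, obj), (cds, obj)
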