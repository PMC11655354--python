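"""Marker scanning, growth ratios, capacity, and the growth mixed model."""

import numpy as np
import pandas as pd
import pytest
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from extremesoil.growth import (
    GrowthLMM,
    MarkerDB,
    default_marker_db,
    growth_capacity,
    read_sequences,
    relative_growth,
    scan_markers,
)
from extremesoil.simulate import (
    SYNTHETIC_DIF_MOTIF,
    SYNTHETIC_DNAA_PEPTIDE,
    GenomeModel,
    simulate_marker_reads,
    write_fasta,
    write_fastq,
)
from extremesoil.simulate.reads import _encode_peptide

BLOSUM = substitution_matrices.load("BLOSUM62")


# -- independent brute-force oracles ----------------------------------------


def _brute_origin_hit(seq, peptides, k=12, min_score=40.0):
    def frames(s):
        rc = str(Seq(s).reverse_complement())
        out = []
        for x in (s, rc):
            for off in range(3):
                sub = x[off : off + 3 * ((len(x) - off) // 3)]
                out.append(str(Seq(sub).translate()))
        return out

    def pair(a, b):
        try:
            return BLOSUM[a, b]
        except (KeyError, IndexError):
            return -4.0

    for frame in frames(seq):
        for pep in peptides:
            for q in range(len(frame) - k + 1):
                for m in range(len(pep) - k + 1):
                    if frame[q : q + k] != pep[m : m + k]:
                        continue
                    score = sum(pair(frame[q + i], pep[m + i]) for i in range(k))
                    left = right = 0.0
                    run = 0.0
                    i, j = q - 1, m - 1
                    while i >= 0 and j >= 0:
                        run += pair(frame[i], pep[j])
                        left = max(left, run)
                        i, j = i - 1, j - 1
                    run = 0.0
                    i, j = q + k, m + k
                    while i < len(frame) and j < len(pep):
                        run += pair(frame[i], pep[j])
                        right = max(right, run)
                        i, j = i + 1, j + 1
                    if score + left + right >= min_score:
                        return True
    return False


def _brute_terminus_hit(seq, motifs, max_mm=4):
    rc = str(Seq(seq).reverse_complement())
    for strand in (seq, rc):
        for motif in motifs:
            for start in range(len(strand) - 28 + 1):
                window = strand[start : start + 28]
                if sum(a != b for a, b in zip(window, motif)) <= max_mm:
                    return True
    return False


@pytest.fixture(scope="module")
def simulated_reads():
    genome = GenomeModel(rho=1.0, seed=4)
    return simulate_marker_reads(genome, n_reads=1000, seed=8)


class TestMarkerDB:
    def test_validation(self):
        with pytest.raises(ValueError):
            MarkerDB({"bad": "MXZ123"}, {})
        with pytest.raises(ValueError):
            MarkerDB({}, {"short": "ACGT"})
        db = default_marker_db()
        assert len(next(iter(db.terminus_motifs.values()))) == 28


class TestScanning:
    def test_verbatim_planted_fragment_is_origin_hit(self):
        cds = _encode_peptide(SYNTHETIC_DNAA_PEPTIDE[10:60])
        read = "ACGT" + cds[:140]
        assert scan_markers([("r", read)], mode="origin") == 1

    def test_random_read_without_motif_is_terminus_nonhit(self, rng):
        read = "".join(rng.choice(list("ACGT"), 150))
        hits = scan_markers([("r", read)], mode="terminus", max_mismatches=0)
        assert hits == 0

    def test_origin_scan_matches_brute_force(self, simulated_reads):
        db = default_marker_db()
        subset = simulated_reads[:300]
        fast = scan_markers(subset, db, mode="origin")
        brute = sum(
            _brute_origin_hit(seq, list(db.origin_peptides.values()))
            for _, seq in subset
        )
        assert fast == brute

    def test_terminus_scan_matches_brute_force(self, simulated_reads):
        db = default_marker_db()
        subset = simulated_reads[:300]
        fast = scan_markers(subset, db, mode="terminus")
        brute = sum(
            _brute_terminus_hit(seq, list(db.terminus_motifs.values()))
            for _, seq in subset
        )
        assert fast == brute

    def test_invariant_to_read_order(self, simulated_reads):
        subset = simulated_reads[:200]
        assert scan_markers(subset, mode="origin") == scan_markers(
            subset[::-1], mode="origin"
        )

    def test_terminus_invariant_to_reverse_complement(self, simulated_reads):
        subset = simulated_reads[:200]
        rc = [(rid, str(Seq(s).reverse_complement())) for rid, s in subset]
        assert scan_markers(subset, mode="terminus") == scan_markers(
            rc, mode="terminus"
        )

    def test_reads_from_fasta_and_fastq_files(self, simulated_reads, tmp_path):
        subset = simulated_reads[:50]
        fa, fq = tmp_path / "r.fasta", tmp_path / "r.fastq"
        write_fasta(subset, fa)
        write_fastq(subset, fq)
        assert read_sequences(fa) == subset
        assert read_sequences(fq) == subset
        assert scan_markers(fa, mode="terminus") == scan_markers(
            subset, mode="terminus"
        )

    def test_invalid_alphabet_rejected(self):
        with pytest.raises(ValueError):
            scan_markers([("r", "ACGU-XYZ")], mode="origin")
        with pytest.raises(ValueError):
            scan_markers([], mode="origin")


class TestRelativeGrowth:
    def _meta(self):
        return pd.DataFrame(
            {
                "sample_id": ["heat", "ctrl"],
                "country": "AA",
                "site": "x",
                "treatment": ["heat", "control"],
                "sampling": "S1",
                "day": 0,
            }
        )

    def test_equal_ratios_give_zero(self):
        counts = pd.DataFrame(
            {"sample_id": ["heat", "ctrl"], "O": [40, 20], "T": [20, 10]}
        )
        out = relative_growth(counts, self._meta(), pseudocount=0.0)
        assert out["G_rel"].iloc[0] == pytest.approx(0.0)

    def test_doubled_treatment_ratio_gives_one(self):
        counts = pd.DataFrame(
            {"sample_id": ["heat", "ctrl"], "O": [40, 20], "T": [10, 10]}
        )
        out = relative_growth(counts, self._meta(), pseudocount=0.0)
        assert out["G_rel"].iloc[0] == pytest.approx(1.0)

    def test_zero_terminus_stays_finite_via_pseudocount(self):
        counts = pd.DataFrame(
            {"sample_id": ["heat", "ctrl"], "O": [40, 20], "T": [0, 10]}
        )
        out = relative_growth(counts, self._meta())
        assert np.isfinite(out["G_rel"].iloc[0])

    def test_missing_pair_warns(self):
        counts = pd.DataFrame({"sample_id": ["heat"], "O": [10], "T": [5]})
        meta = self._meta().iloc[[0]]
        with pytest.warns(UserWarning):
            out = relative_growth(counts, meta)
        assert out.empty

    def test_rho_recovery_is_monotone_in_planted_gradient(self):
        """Mean origin:terminus growth estimate increases with the planted
        peak-to-trough gradient difference from control."""
        db = default_marker_db()

        def pooled_log_ratio(rho, seeds):
            # small genome (denser marker windows) + pooled replicates keep
            # the counting noise well below the 0.5 grid spacing
            o = t = 0
            for s in seeds:
                reads = simulate_marker_reads(
                    GenomeModel(length=5000, rho=rho, seed=6), 4000, seed=s
                )
                o += scan_markers(reads, db, mode="origin")
                t += scan_markers(reads, db, mode="terminus")
            return np.log2((o + 0.5) / (t + 0.5))

        base = pooled_log_ratio(0.0, (60, 61, 62))
        values = [
            pooled_log_ratio(rho, (70 + int(4 * rho), 80 + int(4 * rho), 90 + int(4 * rho)))
            - base
            for rho in (0.0, 0.5, 1.0, 1.5)
        ]
        assert values == sorted(values)


class TestGrowthCapacity:
    def _meta(self):
        return pd.DataFrame(
            {
                "sample_id": ["a", "c"],
                "site": "x",
                "country": "AA",
                "treatment": ["heat", "control"],
                "sampling": "S1",
            }
        )

    def test_unit_copy_numbers_give_unit_mean_and_zero_delta(self):
        table = pd.DataFrame([[5, 5], [2, 8]], index=["a", "c"], columns=["t1", "t2"])
        cn = pd.Series([1.0, 1.0], index=["t1", "t2"])
        out = growth_capacity(table, cn, self._meta()).set_index("sample_id")
        assert out.loc["a", "capacity"] == pytest.approx(1.0)
        assert out.loc["a", "delta_capacity"] == pytest.approx(0.0)

    def test_equal_abundance_hand_calculation(self):
        table = pd.DataFrame([[5, 5]], index=["a"], columns=["t1", "t2"])
        cn = pd.Series([1.0, 3.0], index=["t1", "t2"])
        meta = self._meta().iloc[[0]]
        out = growth_capacity(table, cn, meta)
        assert out["capacity"].iloc[0] == pytest.approx(2.0)

    def test_more_high_copy_abundance_raises_mean(self):
        cn = pd.Series([1.0, 3.0], index=["t1", "t2"])
        meta = self._meta().iloc[[0]]
        low = growth_capacity(
            pd.DataFrame([[8, 2]], index=["a"], columns=["t1", "t2"]), cn, meta
        )["capacity"].iloc[0]
        high = growth_capacity(
            pd.DataFrame([[2, 8]], index=["a"], columns=["t1", "t2"]), cn, meta
        )["capacity"].iloc[0]
        assert high > low

    def test_no_overlapping_taxa_errors(self):
        table = pd.DataFrame([[1]], index=["a"], columns=["t1"])
        with pytest.raises(ValueError):
            growth_capacity(table, pd.Series([2.0], index=["zz"]), self._meta())

    def test_copy_numbers_below_one_rejected(self):
        table = pd.DataFrame([[1]], index=["a"], columns=["t1"])
        with pytest.raises(ValueError):
            growth_capacity(table, pd.Series([0.5], index=["t1"]), self._meta())


class TestGrowthModel:
    def _data(self, seed, effect=1.5):
        from extremesoil.design import build_design, records_to_frame

        rng = np.random.default_rng(seed)
        meta = records_to_frame(build_design(6).records("metagenome"))
        g = meta.dropna(subset=["treatment"])
        g = g[(g["sampling"].isin(["S1", "S4"])) & (g["treatment"] != "control")].copy()
        g["d_bact"] = rng.uniform(0.1, 0.6, len(g))
        g["d_fung"] = rng.uniform(0.1, 0.6, len(g))
        g["G_rel"] = (
            0.2
            + effect * g["d_fung"] * (g["treatment"] == "heat")
            + rng.normal(0, 0.15, len(g))
        )
        return g

    def test_minimal_model_nested_in_full(self):
        res = GrowthLMM(self._data(3)).fit()
        assert res.converged
        assert set(res.minimal_terms) <= set(res.full_terms)
        assert res.aic_path[0][0] == "<full>"

    def test_planted_fungal_interaction_retained_with_positive_heat_slope(self):
        res = GrowthLMM(self._data(4)).fit()
        assert "treatment:d_fung" in res.minimal_terms
        heat = [n for n in res.coef.index if "heat" in n and "d_fung" in n]
        assert res.coef.loc[heat[0], "estimate"] > 0

    def test_null_interaction_usually_dropped(self):
        dropped = 0
        for s in range(5):
            res = GrowthLMM(self._data(10 + s, effect=0.0)).fit()
            dropped += "treatment:d_fung" not in res.minimal_terms
        assert dropped >= 3

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError):
            GrowthLMM(pd.DataFrame({"G_rel": [1.0]}))


def test_marker_db_round_trips_through_fasta(tmp_path):
    db = default_marker_db()
    ori, ter = tmp_path / "ori.faa", tmp_path / "ter.fna"
    ori.write_text(
        "".join(f">{n}\n{s}\n" for n, s in db.origin_peptides.items())
    )
    ter.write_text(
        "".join(f">{n}\n{s}\n" for n, s in db.terminus_motifs.items())
    )
    loaded = MarkerDB.from_fasta(ori, ter)
    assert loaded.origin_peptides == db.origin_peptides
    assert loaded.terminus_motifs == db.terminus_motifs
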