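"""Community bacterial growth from origin/terminus markers.

Replicating chromosomes carry more copies of origin-proximal loci, so the
ratio of reads hitting an origin marker (dnaA, the replication initiator
protein) to reads hitting a terminus marker (the 28-bp dif
chromosome-dimer-resolution site) indexes the fraction of actively growing
cells.  Relative growth of a disturbed sample is the difference of
log2(origin hits / terminus hits) from its paired control.

Origin hits use a translated seed-and-extend search: a read hits when any of
its six reading frames shares an exact length-k peptide with a marker and an
ungapped BLOSUM62 extension reaches the score threshold.  Terminus hits use
a mismatch-tolerant scan of every read window (both strands) against the
28-bp motifs.  Each read counts at most once per mode.

Growth capacity is the abundance-weighted mean 16S copy number per sample
(copy numbers are inputs), compared against the paired control.  The growth
mixed model relates relative growth to treatment, time and the bacterial and
fungal community displacements from control, with backward-AIC reduction.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .simulate.reads import SYNTHETIC_DIF_MOTIF, SYNTHETIC_DNAA_PEPTIDE

__all__ = [
    "MarkerDB",
    "default_marker_db",
    "read_sequences",
    "scan_markers",
    "relative_growth",
    "growth_capacity",
    "GrowthLMM",
    "GrowthLMMResults",
]

_AA = set("ACDEFGHIKLMNPQRSTVWY")
_COMPLEMENT = bytes.maketrans(b"ACGTN", b"TGCAN")


@dataclass(frozen=True)
class MarkerDB:
    """Origin markers (replication-initiator peptides) and terminus markers
    (28-bp nucleotide motifs)."""

    origin_peptides: dict[str, str]
    terminus_motifs: dict[str, str]

    def __post_init__(self) -> None:
        for name, pep in self.origin_peptides.items():
            if not set(pep) <= _AA:
                raise ValueError(f"origin marker {name!r} has non-amino-acid letters")
        for name, motif in self.terminus_motifs.items():
            if len(motif) != 28 or not set(motif) <= set("ACGT"):
                raise ValueError(f"terminus marker {name!r} must be 28 bp of ACGT")

    @classmethod
    def from_fasta(cls, origin_path, terminus_path) -> "MarkerDB":
        """Load origin peptides and terminus motifs from FASTA files."""
        from Bio import SeqIO

        origins = {
            rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(origin_path), "fasta")
        }
        termini = {
            rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(terminus_path), "fasta")
        }
        return cls(origins, termini)


def default_marker_db() -> MarkerDB:
    """Toy marker database built from the synthetic sequences the read
    simulator plants (stand-ins, not curated database entries)."""
    return MarkerDB(
        origin_peptides={"dnaA_syn": SYNTHETIC_DNAA_PEPTIDE},
        terminus_motifs={"dif_syn": SYNTHETIC_DIF_MOTIF},
    )


def read_sequences(source) -> list[tuple[str, str]]:
    """Load reads from (id, seq) pairs or a FASTA/FASTQ path (.gz ok)."""
    if not isinstance(source, (str, Path)):
        return list(source)
    path = Path(source)
    opener = gzip.open if path.suffix == ".gz" else open
    name = path.name[:-3] if path.suffix == ".gz" else path.name
    reads = []
    with opener(path, "rt") as fh:
        first = fh.read(1)
        fh.seek(0)
        if first == ">":
            rid, chunks = None, []
            for line in fh:
                line = line.strip()
                if line.startswith(">"):
                    if rid is not None:
                        reads.append((rid, "".join(chunks)))
                    rid, chunks = line[1:].split()[0], []
                elif line:
                    chunks.append(line)
            if rid is not None:
                reads.append((rid, "".join(chunks)))
        elif first == "@":
            while True:
                header = fh.readline().strip()
                if not header:
                    break
                seq = fh.readline().strip()
                fh.readline()
                fh.readline()
                reads.append((header[1:].split()[0], seq))
        else:
            raise ValueError(f"unrecognized read format in {name}")
    return reads


# -- origin (translated) scan ------------------------------------------------

_BLOSUM = substitution_matrices.load("BLOSUM62")


def _score(a: str, b: str) -> float:
    try:
        return _BLOSUM[a, b]
    except (KeyError, IndexError):
        return -4.0


def _six_frames(seq: str) -> list[str]:
    rc = str(Seq(seq).reverse_complement())
    frames = []
    for s in (seq, rc):
        for off in range(3):
            sub = s[off : off + 3 * ((len(s) - off) // 3)]
            frames.append(str(Seq(sub).translate()))
    return frames


def _extend(query: str, qpos: int, marker: str, mpos: int, k: int) -> float:
    """Ungapped extension score around an exact k-mer seed (best cumulative
    BLOSUM62 sums to either side; never below the seed score alone)."""
    score = sum(_score(query[qpos + i], marker[mpos + i]) for i in range(k))
    best = 0.0
    run = 0.0
    i, j = qpos - 1, mpos - 1
    while i >= 0 and j >= 0:
        run += _score(query[i], marker[j])
        best = max(best, run)
        i, j = i - 1, j - 1
    score += best
    best = run = 0.0
    i, j = qpos + k, mpos + k
    while i < len(query) and j < len(marker):
        run += _score(query[i], marker[j])
        best = max(best, run)
        i, j = i + 1, j + 1
    return score + best


def _scan_origin(
    reads: list[tuple[str, str]], db: MarkerDB, k: int, min_score: float
) -> int:
    index: dict[str, list[tuple[str, int]]] = {}
    for name, pep in db.origin_peptides.items():
        for pos in range(len(pep) - k + 1):
            index.setdefault(pep[pos : pos + k], []).append((name, pos))
    hits = 0
    for _, seq in reads:
        hit = False
        for frame in _six_frames(seq):
            if hit:
                break
            for qpos in range(len(frame) - k + 1):
                seeds = index.get(frame[qpos : qpos + k])
                if not seeds:
                    continue
                for name, mpos in seeds:
                    if _extend(frame, qpos, db.origin_peptides[name], mpos, k) >= min_score:
                        hit = True
                        break
                if hit:
                    break
        hits += hit
    return hits


# -- terminus (motif) scan ---------------------------------------------------


def _scan_terminus(
    reads: list[tuple[str, str]], db: MarkerDB, max_mismatches: int
) -> int:
    motifs = []
    for motif in db.terminus_motifs.values():
        motifs.append(np.frombuffer(motif.encode(), dtype=np.uint8))
        rc = motif.encode().translate(_COMPLEMENT)[::-1]
        motifs.append(np.frombuffer(rc, dtype=np.uint8))
    by_length: dict[int, list[int]] = {}
    seqs = [seq for _, seq in reads]
    for i, seq in enumerate(seqs):
        by_length.setdefault(len(seq), []).append(i)
    hit = np.zeros(len(seqs), dtype=bool)
    for length, idx in by_length.items():
        if length < 28:
            continue
        block = np.frombuffer(
            "".join(seqs[i] for i in idx).encode(), dtype=np.uint8
        ).reshape(len(idx), length)
        windows = np.lib.stride_tricks.sliding_window_view(block, 28, axis=1)
        any_hit = np.zeros(len(idx), dtype=bool)
        for motif in motifs:
            mm = (windows != motif).sum(axis=2)
            any_hit |= (mm <= max_mismatches).any(axis=1)
        hit[idx] = any_hit
    return int(hit.sum())


def scan_markers(
    reads,
    db: MarkerDB | None = None,
    mode: str = "origin",
    k: int = 12,
    min_score: float = 40.0,
    max_mismatches: int = 4,
) -> int:
    """Count reads with at least one qualifying marker match.

    ``mode='origin'`` runs the translated seed-and-extend search against the
    peptide markers; ``mode='terminus'`` the mismatch-tolerant 28-bp motif
    scan on both strands.
    """
    reads = read_sequences(reads)
    if not reads:
        raise ValueError("no reads supplied")
    for _, seq in reads[:100]:
        if not set(seq) <= set("ACGTN"):
            raise ValueError("reads must be DNA over ACGTN")
    if db is None:
        db = default_marker_db()
    if mode == "origin":
        return _scan_origin(reads, db, k, min_score)
    if mode == "terminus":
        return _scan_terminus(reads, db, max_mismatches)
    raise ValueError(f"unknown mode {mode!r}")


# -- growth estimates --------------------------------------------------------


def relative_growth(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """log2 origin:terminus ratio of each disturbed sample minus its paired
    control (same site and sampling).

    ``counts`` holds one row per sample with columns ``sample_id``, ``O``
    (origin hits) and ``T`` (terminus hits); the pseudocount is applied
    symmetrically to all four counts so zero terminus hits stay finite.
    Samples without a control pair are skipped with a warning.
    """
    meta = metadata.set_index("sample_id") if "sample_id" in metadata.columns else metadata
    cnt = counts.set_index("sample_id") if "sample_id" in counts.columns else counts
    if (cnt[["O", "T"]] < 0).to_numpy().any():
        raise ValueError("negative marker counts")
    meta = meta.loc[meta.index.intersection(cnt.index)]
    controls = meta[meta["treatment"] == "control"]
    rows = []
    for sid, rec in meta.iterrows():
        if rec["treatment"] in (None, "control") or pd.isna(rec["treatment"]):
            continue
        pair = controls[
            (controls["site"] == rec["site"]) & (controls["sampling"] == rec["sampling"])
        ]
        if pair.empty:
            warnings.warn(f"no control pair for {sid}; skipped", stacklevel=2)
            continue
        cid = pair.index[0]
        log_ratio = np.log2(
            (cnt.loc[sid, "O"] + pseudocount) / (cnt.loc[sid, "T"] + pseudocount)
        )
        log_ratio_c = np.log2(
            (cnt.loc[cid, "O"] + pseudocount) / (cnt.loc[cid, "T"] + pseudocount)
        )
        rows.append(
            {
                "sample_id": sid,
                "control_id": cid,
                "country": rec["country"],
                "site": rec["site"],
                "treatment": rec["treatment"],
                "sampling": rec["sampling"],
                "day": rec["day"],
                "O": cnt.loc[sid, "O"],
                "T": cnt.loc[sid, "T"],
                "G_rel": log_ratio - log_ratio_c,
            }
        )
    return pd.DataFrame(rows)


def growth_capacity(
    table: pd.DataFrame,
    copy_numbers: pd.Series,
    metadata: pd.DataFrame,
) -> pd.DataFrame:
    """Abundance-weighted mean 16S copy number per sample and its difference
    from the paired control (same site and sampling)."""
    shared = [t for t in table.columns if t in copy_numbers.index]
    if not shared:
        raise ValueError("no taxa with copy-number estimates")
    cn = copy_numbers.loc[shared].to_numpy(dtype=float)
    if (cn < 1).any():
        raise ValueError("copy numbers must be >= 1")
    ab = table[shared].to_numpy(dtype=float)
    weights = ab.sum(axis=1)
    capacity = pd.Series(
        (ab @ cn) / np.where(weights > 0, weights, np.nan), index=table.index
    )
    meta = metadata.set_index("sample_id") if "sample_id" in metadata.columns else metadata
    meta = meta.loc[meta.index.intersection(capacity.index)]
    controls = meta[meta["treatment"] == "control"]
    rows = []
    for sid, rec in meta.iterrows():
        if pd.isna(rec["treatment"]):
            continue
        entry = {
            "sample_id": sid,
            "site": rec["site"],
            "treatment": rec["treatment"],
            "sampling": rec["sampling"],
            "capacity": capacity[sid],
            "delta_capacity": np.nan,
        }
        if rec["treatment"] != "control":
            pair = controls[
                (controls["site"] == rec["site"])
                & (controls["sampling"] == rec["sampling"])
            ]
            if not pair.empty:
                entry["delta_capacity"] = capacity[sid] - capacity[pair.index[0]]
        rows.append(entry)
    return pd.DataFrame(rows)


# -- growth mixed model ------------------------------------------------------

FULL_TERMS = (
    "treatment",
    "day",
    "d_bact",
    "d_fung",
    "treatment:day",
    "treatment:d_bact",
    "treatment:d_fung",
    "d_bact:d_fung",
)


@dataclass
class GrowthLMMResults:
    full_terms: tuple[str, ...]
    minimal_terms: tuple[str, ...]
    coef: pd.DataFrame
    aic_path: list[tuple[str, float]] = field(default_factory=list)
    converged: bool = True

    def summary(self) -> str:
        lines = [
            "Growth mixed model (relative log2 origin:terminus vs control)",
            f"  full terms:    {', '.join(self.full_terms)}",
            f"  minimal terms: {', '.join(self.minimal_terms)}",
            self.coef.round(4).to_string(),
        ]
        return "\n".join(lines)


class GrowthLMM:
    """Mixed model of relative growth with backward-AIC term selection.

    ``data`` is the output of :func:`relative_growth` joined with the
    bacterial/fungal community displacement columns ``d_bact``/``d_fung``
    (Bray-Curtis dissimilarity from the paired control).  Random intercepts
    for site within country; residual variance differs by treatment
    (iterated weighting).  The full model carries main effects plus all
    two-way interactions among treatment, day and the two distances;
    backward selection (ML fits, AIC) respects marginality, and the minimal
    model is refitted by REML.
    """

    def __init__(self, data: pd.DataFrame, weight_iterations: int = 1):
        required = {"G_rel", "treatment", "day", "d_bact", "d_fung", "country", "site"}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"growth data missing columns {sorted(missing)}")
        self.data = data.reset_index(drop=True)
        self.treatments = sorted(self.data["treatment"].unique())
        self.weight_iterations = weight_iterations

    def _columns_for(self, term: str) -> dict[str, np.ndarray]:
        d = self.data
        tdum = {
            t: (d["treatment"] == t).to_numpy(dtype=float) for t in self.treatments[1:]
        }
        basics: dict[str, dict[str, np.ndarray]] = {
            "treatment": {f"treatment[{t}]": v for t, v in tdum.items()},
            "day": {"day": d["day"].to_numpy(dtype=float)},
            "d_bact": {"d_bact": d["d_bact"].to_numpy(dtype=float)},
            "d_fung": {"d_fung": d["d_fung"].to_numpy(dtype=float)},
        }
        if ":" not in term:
            return basics[term]
        a, b = term.split(":")
        out = {}
        for na, va in basics[a].items():
            for nb, vb in basics[b].items():
                out[f"{na}:{nb}"] = va * vb
        return out

    def _fit_terms(self, terms: tuple[str, ...], w: np.ndarray, reml: bool):
        d = self.data
        inv_w = 1.0 / w
        cols = {"x_int": np.ones(len(d))}
        for term in terms:
            cols.update(self._columns_for(term))
        frame = pd.DataFrame({k: v * inv_w for k, v in cols.items()})
        xnames = [c.replace("[", "_").replace("]", "").replace(":", "_X_").replace(".", "_")
                  for c in cols]
        frame.columns = xnames
        frame["ystar"] = d["G_rel"].to_numpy() * inv_w
        frame["inv_w"] = inv_w
        frame["country"] = d["country"].to_numpy()
        frame["site"] = d["site"].to_numpy()
        formula = "ystar ~ 0 + " + " + ".join(xnames)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore", UserWarning)
            model = MixedLM.from_formula(
                formula,
                frame,
                groups="country",
                re_formula="0 + inv_w",
                vc_formula={"site": "0 + C(site):inv_w"},
            )
            res = model.fit(reml=reml, method="lbfgs", maxiter=500)
            if not res.converged:  # quasi-Newton can stall near a boundary
                res = model.fit(reml=reml, method="powell", maxiter=400)
        return res, list(cols.keys())

    @staticmethod
    def _aic(res) -> float:
        k = len(res.fe_params) + res.cov_re.shape[0] + len(res.vcomp) + 1
        return float(-2 * res.llf + 2 * k)

    @staticmethod
    def _removable(terms: tuple[str, ...]) -> list[str]:
        out = []
        for term in terms:
            if ":" in term:
                out.append(term)
            else:
                in_interaction = any(
                    ":" in t and term in t.split(":") for t in terms
                )
                if not in_interaction:
                    out.append(term)
        return out

    def fit(self) -> GrowthLMMResults:
        d = self.data
        w = np.ones(len(d))
        try:
            for _ in range(self.weight_iterations):
                res, _ = self._fit_terms(FULL_TERMS, w, reml=True)
                resid = np.asarray(res.resid) * w
                by_t = pd.Series(np.abs(resid)).groupby(d["treatment"].to_numpy()).mean()
                mult = (by_t / by_t.mean()).clip(0.25, 4.0)
                w = d["treatment"].map(mult).to_numpy()

            terms = tuple(FULL_TERMS)
            current, _ = self._fit_terms(terms, w, reml=False)
            path = [("<full>", self._aic(current))]
            improved = True
            while improved and terms:
                improved = False
                best_drop, best_aic = None, self._aic(current) - 1e-9
                for term in self._removable(terms):
                    reduced = tuple(t for t in terms if t != term)
                    try:
                        cand, _ = self._fit_terms(reduced, w, reml=False)
                    except (np.linalg.LinAlgError, ValueError):
                        continue
                    if self._aic(cand) < best_aic:
                        best_drop, best_aic, best_res = term, self._aic(cand), cand
                if best_drop is not None:
                    terms = tuple(t for t in terms if t != best_drop)
                    current = best_res
                    path.append((f"-{best_drop}", best_aic))
                    improved = True

            final, names = self._fit_terms(terms, w, reml=True)
        except (np.linalg.LinAlgError, ValueError):
            return GrowthLMMResults(FULL_TERMS, (), pd.DataFrame(), [], False)
        params = np.asarray(final.fe_params)
        bse = np.asarray(final.bse_fe)
        df_resid = max(len(d) - len(params), 1)
        coef = pd.DataFrame(
            {
                "estimate": params,
                "se": bse,
                "t": params / bse,
                "df": df_resid,
                "p": 2 * stats.t.sf(np.abs(params / bse), df_resid),
            },
            index=names,
        )
        return GrowthLMMResults(
            full_terms=FULL_TERMS,
            minimal_terms=terms,
            coef=coef,
            aic_path=path,
            converged=bool(final.converged),
        )
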