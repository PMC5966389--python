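"""Association-network and symptom-profile containers plus their TSV I/O.

The central object is :class:`AssociationNetwork`: a binary disease x microbe
adjacency matrix ``A`` with ordered label maps.  ``A[i, j] == 1`` iff disease
``i`` has a recorded association with microbe ``j``.  Rows of ``A`` are disease
interaction profiles, columns are microbe interaction profiles; both feed the
Gaussian kernel in :mod:`ncphmda.similarity`.

All file formats are plain TSV so fixtures generated by :mod:`ncphmda.synthetic`
round-trip through the same loaders real exports use.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AlignmentError, EdgeListFormatError, EmptyEdgeListError

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationNetwork",
    "SymptomProfile",
    "NetworkStats",
    "load_association_edgelist",
    "load_symptom_similarity",
    "load_symptom_counts",
    "network_stats",
    "write_association_edgelist",
    "write_ranked_predictions",
]


def _canon(label: str) -> str:
    """Canonical comparison key: trimmed, case-folded."""
    return str(label).strip().lower()


def _unique_ordered(labels, order: str = "first") -> list[str]:
    """Deduplicate labels (case-insensitively) keeping first-seen casing.

    order='first' keeps first-appearance order; 'lex' sorts by canonical key.
    """
    seen: dict[str, str] = {}
    for lab in labels:
        key = _canon(lab)
        if key not in seen:
            seen[key] = str(lab).strip()
    out = list(seen.values())
    if order == "lex":
        out.sort(key=_canon)
    elif order != "first":
        raise ValueError(f"unknown label order {order!r}")
    return out


@dataclass
class AssociationNetwork:
    """Binary bipartite disease-microbe association network.

    Attributes
    ----------
    diseases, microbes : list of str
        Ordered row/column labels.
    A : ndarray of shape (n_diseases, n_microbes)
        Binary adjacency matrix.
    label_order : str
        'first' (first appearance) or 'lex'; recorded for reproducibility.
    """

    diseases: list[str]
    microbes: list[str]
    A: np.ndarray
    label_order: str = "first"

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        if self.A.shape != (len(self.diseases), len(self.microbes)):
            raise AlignmentError(
                f"A has shape {self.A.shape}, labels imply "
                f"({len(self.diseases)}, {len(self.microbes)})"
            )
        if not np.isin(self.A, (0.0, 1.0)).all():
            raise ValueError("adjacency entries must be exactly 0 or 1")
        for labs, kind in ((self.diseases, "disease"), (self.microbes, "microbe")):
            keys = [_canon(x) for x in labs]
            if len(set(keys)) != len(keys):
                raise ValueError(f"duplicate {kind} labels")

    @property
    def n_diseases(self) -> int:
        return len(self.diseases)

    @property
    def n_microbes(self) -> int:
        return len(self.microbes)

    @property
    def n_associations(self) -> int:
        return int(self.A.sum())

    def disease_index(self, label: str) -> int:
        return self._dindex()[_canon(label)]

    def microbe_index(self, label: str) -> int:
        return self._mindex()[_canon(label)]

    def _dindex(self) -> dict[str, int]:
        return {_canon(l): i for i, l in enumerate(self.diseases)}

    def _mindex(self) -> dict[str, int]:
        return {_canon(l): j for j, l in enumerate(self.microbes)}

    def edges(self) -> list[tuple[int, int]]:
        """Known associations as (disease_index, microbe_index) pairs."""
        ii, jj = np.nonzero(self.A)
        return list(zip(ii.tolist(), jj.tolist()))

    def copy(self) -> "AssociationNetwork":
        return AssociationNetwork(
            list(self.diseases), list(self.microbes), self.A.copy(), self.label_order
        )


@dataclass
class SymptomProfile:
    """Disease x symptom co-occurrence counts (term co-occurrence matrix W)."""

    diseases: list[str]
    symptoms: list[str]
    W: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.W.shape != (len(self.diseases), len(self.symptoms)):
            raise AlignmentError("W shape does not match label counts")
        if (self.W < 0).any():
            raise ValueError("co-occurrence counts must be non-negative")

    @property
    def n_diseases(self) -> int:
        return len(self.diseases)

    @property
    def n_symptoms(self) -> int:
        return len(self.symptoms)


@dataclass
class NetworkStats:
    """Global characteristics of an association network (Table-1 style)."""

    n_diseases: int
    n_microbes: int
    n_associations: int
    mean_microbe_degree: float
    mean_disease_degree: float
    microbe_degree_histogram: dict[int, int] = field(default_factory=dict)
    disease_degree_histogram: dict[int, int] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "n_diseases": self.n_diseases,
            "n_microbes": self.n_microbes,
            "n_associations": self.n_associations,
            "mean_microbe_degree": round(self.mean_microbe_degree, 6),
            "mean_disease_degree": round(self.mean_disease_degree, 6),
            "microbe_degree_histogram": dict(sorted(self.microbe_degree_histogram.items())),
            "disease_degree_histogram": dict(sorted(self.disease_degree_histogram.items())),
        }


def _read_table(path: str | Path, min_cols: int) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str,
                         skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise EmptyEdgeListError(f"{path}: no records found") from None
    if df.shape[1] < min_cols:
        raise EdgeListFormatError(
            f"{path}: expected at least {min_cols} tab-separated columns, "
            f"found {df.shape[1]}"
        )
    return df


def _strip_header(df: pd.DataFrame, header_words: tuple[str, ...]) -> pd.DataFrame:
    """Drop the first row if it looks like a column header."""
    first = [_canon(x) for x in df.iloc[0]]
    if any(w in first for w in header_words):
        return df.iloc[1:].reset_index(drop=True)
    return df


def load_association_edgelist(path: str | Path, order: str = "first") -> AssociationNetwork:
    """Read a (disease, microbe) TSV edge list into an :class:`AssociationNetwork`.

    Lines starting with '#' are comments; an optional header row containing the
    words 'disease'/'microbe' is skipped.  Duplicate edges collapse to a single
    association with a logged warning (mirrors deduplication of repeated
    database entries at load time).
    """
    df = _read_table(path, min_cols=2)
    df = _strip_header(df, ("disease", "microbe"))
    if df.empty:
        raise EmptyEdgeListError(f"{path}: no edges found")
    pairs = [( _canon(d), _canon(m)) for d, m in zip(df[0], df[1])]
    n_dup = len(pairs) - len(set(pairs))
    if n_dup:
        logger.warning("%s: collapsed %d duplicate edge(s)", path, n_dup)
    diseases = _unique_ordered(df[0], order)
    microbes = _unique_ordered(df[1], order)
    dmap = {_canon(l): i for i, l in enumerate(diseases)}
    mmap = {_canon(l): j for j, l in enumerate(microbes)}
    A = np.zeros((len(diseases), len(microbes)))
    for d, m in pairs:
        A[dmap[d], mmap[m]] = 1.0
    net = AssociationNetwork(diseases, microbes, A, label_order=order)
    logger.info(
        "%s: %d diseases, %d microbes, %d associations",
        path, net.n_diseases, net.n_microbes, net.n_associations,
    )
    return net


def write_association_edgelist(net: AssociationNetwork, path: str | Path) -> None:
    """Write the network back out as a (disease, microbe) TSV edge list."""
    with open(path, "w") as fh:
        fh.write("#disease\tmicrobe\n")
        for i, j in net.edges():
            fh.write(f"{net.diseases[i]}\t{net.microbes[j]}\n")


def load_symptom_similarity(path: str | Path, coerce: bool = True):
    """Read (disease_a, disease_b, score) triples into a partial similarity matrix.

    Returns a :class:`ncphmda.similarity.SimilarityMatrix` with role ``SS`` whose
    ``mask`` marks pairs that were actually scored; unlisted pairs are ABSENT
    (distinct from an explicit 0).  The diagonal of every listed disease is set
    to 1.  Scores outside [0, 1] raise; a self-pair with score != 1 is coerced
    to 1 with a warning when ``coerce`` is true, otherwise raises.
    """
    from .similarity import SimilarityMatrix  # local import to avoid cycle

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = _read_table(path, min_cols=3)
    except EmptyEdgeListError:
        return SimilarityMatrix(labels=[], S=np.zeros((0, 0)), role="SS",
                                mask=np.zeros((0, 0), dtype=bool))
    df = _strip_header(df, ("disease", "disease_a", "score"))
    labels = _unique_ordered(pd.concat([df[0], df[1]]), "first")
    idx = {_canon(l): i for i, l in enumerate(labels)}
    n = len(labels)
    S = np.zeros((n, n))
    mask = np.zeros((n, n), dtype=bool)
    for a, b, s in zip(df[0], df[1], df[2]):
        score = float(s)
        if not (0.0 <= score <= 1.0):
            raise ValueError(f"{path}: symptom similarity {score} outside [0, 1]")
        i, j = idx[_canon(a)], idx[_canon(b)]
        if i == j and score != 1.0:
            if not coerce:
                raise ValueError(f"{path}: self-pair {a} with score {score} != 1")
            logger.warning("%s: self-pair %s score %s coerced to 1", path, a, score)
            score = 1.0
        S[i, j] = S[j, i] = score
        mask[i, j] = mask[j, i] = True
    np.fill_diagonal(S, 1.0)
    np.fill_diagonal(mask, True)
    return SimilarityMatrix(labels=labels, S=S, role="SS", mask=mask)


def load_symptom_counts(path: str | Path) -> SymptomProfile:
    """Read disease-symptom co-occurrence counts.

    Accepts either long-format triples (disease, symptom, count) or a wide
    matrix whose header row lists symptoms and whose first column lists
    diseases.  The two formats yield identical profiles.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    if df.shape[1] < 2:
        raise EdgeListFormatError(f"{path}: expected at least 2 columns")
    # Long format: exactly 3 columns whose last column is numeric (bar a header
    # row).  Anything else is a wide matrix with a symptom header row.
    long_fmt = df.shape[1] == 3 and all(
        _is_number(v) for v in df.iloc[1:, 2]
    ) and (_is_number(df.iloc[0, 2]) or _canon(df.iloc[0, 2]) in ("count", "n"))
    if not long_fmt:
        symptoms = [str(s).strip() for s in df.iloc[0, 1:]]
        diseases = _unique_ordered(df.iloc[1:, 0], "first")
        W = df.iloc[1:, 1:].astype(float).to_numpy()
    else:
        body = _strip_header(df, ("disease", "symptom", "count"))
        diseases = _unique_ordered(body[0], "first")
        symptoms = _unique_ordered(body[1], "first")
        dmap = {_canon(l): i for i, l in enumerate(diseases)}
        smap = {_canon(l): j for j, l in enumerate(symptoms)}
        W = np.zeros((len(diseases), len(symptoms)))
        for d, s, c in zip(body[0], body[1], body[2]):
            cnt = float(c)
            if cnt < 0:
                raise ValueError(f"{path}: negative count {cnt} for ({d}, {s})")
            W[dmap[_canon(d)], smap[_canon(s)]] += cnt
    if (W < 0).any():
        raise ValueError(f"{path}: negative counts")
    zero_rows = [diseases[i] for i in np.nonzero(W.sum(axis=1) == 0)[0]]
    if zero_rows:
        logger.info("%s: disease(s) with all-zero symptom counts retained: %s",
                    path, ", ".join(zero_rows))
    return SymptomProfile(diseases=diseases, symptoms=symptoms, W=W)


def _is_number(x) -> bool:
    try:
        float(x)
        return True
    except (TypeError, ValueError):
        return False


def network_stats(net: AssociationNetwork) -> NetworkStats:
    """Counts, mean degrees and degree histograms of an association network."""
    mdeg = net.A.sum(axis=0).astype(int)  # per-microbe degree
    ddeg = net.A.sum(axis=1).astype(int)  # per-disease degree
    n_assoc = int(net.A.sum())

    def hist(deg: np.ndarray) -> dict[int, int]:
        vals, counts = np.unique(deg, return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, counts)}

    return NetworkStats(
        n_diseases=net.n_diseases,
        n_microbes=net.n_microbes,
        n_associations=n_assoc,
        mean_microbe_degree=n_assoc / net.n_microbes,
        mean_disease_degree=n_assoc / net.n_diseases,
        microbe_degree_histogram=hist(mdeg),
        disease_degree_histogram=hist(ddeg),
    )


def write_ranked_predictions(scores, net: AssociationNetwork, path: str | Path,
                             top_k: int | None = None) -> None:
    """Write per-disease candidate rankings as TSV.

    Only candidate pairs (A == 0) are ranked, in descending score order with
    ties broken by microbe label (ascending); known pairs are listed after the
    candidates with rank 'NA'.  ``top_k`` caps the number of candidate rows per
    disease.
    """
    S = np.asarray(scores.ncp if hasattr(scores, "ncp") else scores, dtype=float)
    if S.shape != net.A.shape:
        raise AlignmentError(
            f"score matrix shape {S.shape} does not match network {net.A.shape}"
        )
    with open(path, "w") as fh:
        fh.write("# ties broken by microbe label (ascending)\n")
        fh.write("disease\trank\tmicrobe\tscore\tis_known\n")
        for i, disease in enumerate(net.diseases):
            cand = np.nonzero(net.A[i] == 0)[0]
            ordered = sorted(cand, key=lambda j: (-S[i, j], _canon(net.microbes[j])))
            if top_k is not None:
                ordered = ordered[:top_k]
            for rank, j in enumerate(ordered, start=1):
                fh.write(f"{disease}\t{rank}\t{net.microbes[j]}\t{S[i, j]:.6g}\t0\n")
            for j in np.nonzero(net.A[i] == 1)[0]:
                fh.write(f"{disease}\tNA\t{net.microbes[j]}\t{S[i, j]:.6g}\t1\n")
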