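"""Network consistency projection scoring.

The score for a disease-microbe pair projects the microbe-similarity network
and the integrated disease-similarity network onto the known association
network:

    msp(i, j) = <A_i., MS_.j> / ||A_i.||        (microbe space)
    dsp(i, j) = <DS_i., A_.j> / ||A_.j||        (disease space)
    ncp(i, j) = (msp(i, j) + dsp(i, j)) / (||DS_i.|| + ||MS_.j||)

with Euclidean norms throughout.  Zeros of the adjacency matrix are replaced
by a tiny constant delta (default 1e-30) inside the projection arithmetic so
no denominator can vanish; scores are insensitive to delta over many orders
of magnitude.  The method has no tunable parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AlignmentError
from .network_data import AssociationNetwork, SymptomProfile
from .similarity import (
    SimilarityMatrix,
    cosine_symptom_similarity,
    gip_kernel,
    integrate_disease_similarity,
    tfidf_weights,
)

__all__ = [
    "ScoreMatrix",
    "substitute_delta",
    "microbe_space_projection",
    "disease_space_projection",
    "ncp_score",
    "predict",
    "MODES",
]

DEFAULT_DELTA = 1e-30
MODES = ("full", "gip_only", "microbe_space_only", "disease_space_only")


@dataclass
class ScoreMatrix:
    """Disease x microbe projection scores with component matrices retained."""

    diseases: list[str]
    microbes: list[str]
    ncp: np.ndarray
    msp: np.ndarray | None = None
    dsp: np.ndarray | None = None
    delta: float = DEFAULT_DELTA
    mode: str = "full"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ncp = np.asarray(self.ncp, dtype=float)
        if self.ncp.shape != (len(self.diseases), len(self.microbes)):
            raise AlignmentError("score shape does not match labels")
        if not np.isfinite(self.ncp).all():
            raise ValueError("non-finite projection scores")


def substitute_delta(A: np.ndarray, delta: float = DEFAULT_DELTA) -> np.ndarray:
    """Replace zeros of a binary adjacency matrix with ``delta``.

    Guarantees strictly positive row/column norms so the projection
    denominators are always defined.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    A = np.asarray(A, dtype=float)
    return np.where(A == 1.0, 1.0, delta)


def microbe_space_projection(Aprime: np.ndarray, MS: SimilarityMatrix | np.ndarray) -> np.ndarray:
    """Project each microbe's similarity vector onto each disease's association row.

    ``msp[i, j] = <Aprime[i, :], MS[:, j]> / ||Aprime[i, :]||``.
    """
    M = MS.S if isinstance(MS, SimilarityMatrix) else np.asarray(MS, float)
    Aprime = np.asarray(Aprime, dtype=float)
    if Aprime.shape[1] != M.shape[0]:
        raise AlignmentError(
            f"adjacency has {Aprime.shape[1]} microbes, similarity {M.shape[0]}"
        )
    row_norms = np.linalg.norm(Aprime, axis=1)
    return (Aprime @ M) / row_norms[:, None]


def disease_space_projection(Aprime: np.ndarray, DS: SimilarityMatrix | np.ndarray) -> np.ndarray:
    """Project each disease's similarity vector onto each microbe's association column.

    ``dsp[i, j] = <DS[i, :], Aprime[:, j]> / ||Aprime[:, j]||``.
    """
    D = DS.S if isinstance(DS, SimilarityMatrix) else np.asarray(DS, float)
    Aprime = np.asarray(Aprime, dtype=float)
    if Aprime.shape[0] != D.shape[0]:
        raise AlignmentError(
            f"adjacency has {Aprime.shape[0]} diseases, similarity {D.shape[0]}"
        )
    col_norms = np.linalg.norm(Aprime, axis=0)
    return (D @ Aprime) / col_norms[None, :]


def ncp_score(msp: np.ndarray, dsp: np.ndarray,
              DS: SimilarityMatrix | np.ndarray,
              MS: SimilarityMatrix | np.ndarray) -> np.ndarray:
    """Combine the two space projections, normalised by similarity-vector lengths.

    ``ncp[i, j] = (dsp[i, j] + msp[i, j]) / (||DS[i, :]|| + ||MS[:, j]||)``.
    The denominators are strictly positive because similarity diagonals are 1.
    """
    D = DS.S if isinstance(DS, SimilarityMatrix) else np.asarray(DS, float)
    M = MS.S if isinstance(MS, SimilarityMatrix) else np.asarray(MS, float)
    msp = np.asarray(msp, float)
    dsp = np.asarray(dsp, float)
    if msp.shape != dsp.shape:
        raise AlignmentError("msp/dsp shape mismatch")
    ds_norms = np.linalg.norm(D, axis=1)
    ms_norms = np.linalg.norm(M, axis=0)
    return (dsp + msp) / (ds_norms[:, None] + ms_norms[None, :])


def _symptom_to_ss(symptom_input, log_base: float = 10.0) -> SimilarityMatrix | None:
    if symptom_input is None:
        return None
    if isinstance(symptom_input, SimilarityMatrix):
        return symptom_input
    if isinstance(symptom_input, SymptomProfile):
        return cosine_symptom_similarity(tfidf_weights(symptom_input, log_base))
    raise TypeError(f"unsupported symptom input {type(symptom_input)!r}")


def predict(net: AssociationNetwork, symptom_input=None, mode: str = "full",
            delta: float = DEFAULT_DELTA, gamma_prime: float = 1.0,
            log_base: float = 10.0) -> ScoreMatrix:
    """Score every disease-microbe pair of a network.

    Parameters
    ----------
    net
        The association network; its binary matrix drives both kernels.
    symptom_input
        Optional symptom evidence: a precomputed symptom similarity
        (:class:`SimilarityMatrix`, role 'SS'), raw co-occurrence counts
        (:class:`SymptomProfile`), or None.  Without it, 'full' degrades to
        'gip_only'.
    mode
        'full' combines both space projections with the integrated disease
        similarity; 'gip_only' does the same with the GIP disease kernel
        alone; 'microbe_space_only' / 'disease_space_only' keep a single
        projection term normalised by its own similarity-vector length.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    A = net.A
    MS = gip_kernel(A.T, labels=net.microbes, gamma_prime=gamma_prime, role="MS")
    GS = gip_kernel(A, labels=net.diseases, gamma_prime=gamma_prime, role="GS")
    SS = _symptom_to_ss(symptom_input, log_base)
    if mode == "gip_only" or SS is None:
        DS = SimilarityMatrix(list(GS.labels), GS.S.copy(), role="DS",
                              meta={"n_symptom_pairs": 0})
    else:
        DS = integrate_disease_similarity(SS, GS)

    Aprime = substitute_delta(A, delta)
    msp = microbe_space_projection(Aprime, MS)
    dsp = disease_space_projection(Aprime, DS)
    if mode in ("full", "gip_only"):
        scores = ncp_score(msp, dsp, DS, MS)
    elif mode == "microbe_space_only":
        scores = msp / np.linalg.norm(MS.S, axis=0)[None, :]
    else:  # disease_space_only
        scores = dsp / np.linalg.norm(DS.S, axis=1)[:, None]
    return ScoreMatrix(
        diseases=list(net.diseases),
        microbes=list(net.microbes),
        ncp=scores,
        msp=msp,
        dsp=dsp,
        delta=delta,
        mode=mode,
        meta={"gamma_m": MS.meta.get("gamma"), "gamma_d": GS.meta.get("gamma"),
              "n_symptom_pairs": DS.meta.get("n_symptom_pairs", 0)},
    )
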