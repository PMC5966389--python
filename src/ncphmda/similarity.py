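"""Similarity matrices: Gaussian interaction profile kernels, TF-IDF symptom
similarity, and their integration.

Microbe similarity has no curated reference resource, so both microbe and
disease similarity are derived from the association network itself via the
Gaussian interaction profile (GIP) kernel,

    S(a, b) = exp(-gamma * ||p_a - p_b||^2),
    gamma   = gamma' / mean_a ||p_a||^2,

where ``p_a`` is an entity's binary interaction profile (a column of A for a
microbe, a row for a disease) and ``gamma'`` defaults to 1 so the bandwidth is
normalised by the mean number of associations per entity.

Symptom-based disease similarity weights disease-symptom co-occurrence counts
by inverse document frequency, w(i,m) = W(i,m) * log(N / n_m), and takes the
cosine between the resulting disease vectors.  The integrated disease
similarity uses the symptom-based score wherever one exists and falls back to
the GIP kernel elsewhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .errors import AlignmentError, DegenerateNetworkError
from .network_data import SymptomProfile, _canon

logger = logging.getLogger(__name__)

__all__ = [
    "SimilarityMatrix",
    "TfidfWeights",
    "gip_kernel",
    "tfidf_weights",
    "cosine_symptom_similarity",
    "integrate_disease_similarity",
]

_SYMMETRY_TOL = 1e-12


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity matrix over named entities.

    ``role`` records provenance: 'MS' (microbe GIP), 'GS' (disease GIP),
    'SS' (symptom-based), 'DS' (integrated disease).  For role 'SS' the
    boolean ``mask`` marks pairs that actually carry a symptom-based score;
    unmasked pairs are ABSENT and fall back to GS during integration.
    """

    labels: list[str]
    S: np.ndarray
    role: str = "MS"
    mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        n = len(self.labels)
        if self.S.shape != (n, n):
            raise AlignmentError(f"similarity shape {self.S.shape} != ({n}, {n})")
        if n and np.abs(self.S - self.S.T).max() > _SYMMETRY_TOL:
            raise ValueError("similarity matrix is not symmetric")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.S.shape:
                raise AlignmentError("mask shape does not match similarity")

    @property
    def n(self) -> int:
        return len(self.labels)

    def reindex(self, labels: list[str], fill: float = 0.0) -> "SimilarityMatrix":
        """Project onto a new label list; unknown labels get ``fill`` scores
        and (for masked roles) an absent mask."""
        pos = {_canon(l): i for i, l in enumerate(self.labels)}
        idx = [pos.get(_canon(l), -1) for l in labels]
        n = len(labels)
        S = np.full((n, n), fill)
        mask = np.zeros((n, n), dtype=bool)
        src_mask = self.mask if self.mask is not None else np.ones_like(self.S, bool)
        for a, ia in enumerate(idx):
            if ia < 0:
                continue
            for b, ib in enumerate(idx):
                if ib < 0:
                    continue
                S[a, b] = self.S[ia, ib]
                mask[a, b] = src_mask[ia, ib]
        return SimilarityMatrix(list(labels), S, role=self.role, mask=mask,
                                meta=dict(self.meta))


def gip_kernel(profiles: np.ndarray, labels: list[str] | None = None,
               gamma_prime: float = 1.0, role: str = "MS") -> SimilarityMatrix:
    """Gaussian interaction profile kernel over rows of ``profiles``.

    Pass microbe profiles (columns of A, i.e. ``A.T``) for role 'MS' and
    disease profiles (rows of A) for role 'GS'.  The bandwidth is
    ``gamma_prime`` divided by the mean squared profile norm; with binary
    profiles that is the mean association count per entity.

    Raises
    ------
    DegenerateNetworkError
        If every profile is all-zero (bandwidth undefined).
    """
    P = np.asarray(profiles, dtype=float)
    if P.ndim != 2 or P.shape[0] < 1:
        raise ValueError("profiles must be a non-empty 2-D array")
    if gamma_prime <= 0:
        raise ValueError("gamma_prime must be positive")
    mean_sq = float((P ** 2).sum(axis=1).mean())
    if mean_sq == 0.0:
        raise DegenerateNetworkError(
            "all interaction profiles are zero; kernel bandwidth undefined"
        )
    gamma = gamma_prime / mean_sq
    D2 = cdist(P, P, metric="sqeuclidean")
    S = np.exp(-gamma * D2)
    S = (S + S.T) / 2.0
    np.fill_diagonal(S, 1.0)
    if labels is None:
        labels = [f"e{i}" for i in range(P.shape[0])]
    return SimilarityMatrix(list(labels), S, role=role,
                            meta={"gamma": gamma, "gamma_prime": gamma_prime})


@dataclass
class TfidfWeights:
    """TF-IDF-weighted disease-symptom vectors d_i = (w_{i,1}, ..., w_{i,M})."""

    diseases: list[str]
    symptoms: list[str]
    w: np.ndarray
    log_base: float = 10.0

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if self.w.shape != (len(self.diseases), len(self.symptoms)):
            raise AlignmentError("weight shape does not match label counts")


def tfidf_weights(profile: SymptomProfile, log_base: float = 10.0) -> TfidfWeights:
    """Weight co-occurrence counts by inverse document frequency.

    ``w(i,m) = W(i,m) * log(N / n_m)`` with ``n_m`` the number of diseases
    whose count with symptom m is positive.  A symptom occurring with every
    disease gets zero weight; a symptom occurring with none contributes
    nothing either.  The log base (default 10) only rescales all weights, so
    downstream cosine similarity is base-invariant.
    """
    W = profile.W
    N = profile.n_diseases
    n_m = (W > 0).sum(axis=0).astype(float)
    idf = np.zeros_like(n_m)
    nz = n_m > 0
    idf[nz] = np.log(N / n_m[nz]) / np.log(log_base)
    return TfidfWeights(
        diseases=list(profile.diseases),
        symptoms=list(profile.symptoms),
        w=W * idf[np.newaxis, :],
        log_base=log_base,
    )


def cosine_symptom_similarity(weights: TfidfWeights) -> SimilarityMatrix:
    """Cosine similarity between TF-IDF disease vectors (role 'SS').

    A score of 1 means identical symptom profiles, 0 means no shared
    symptoms.  Diseases whose weight vector is all-zero carry no symptom
    information: their similarity to everything (diagonal included) is set to
    0 and the presence mask excludes them, so integration falls back to the
    GIP kernel for those diseases.
    """
    w = weights.w
    norms = np.linalg.norm(w, axis=1)
    nz = norms > 0
    if (~nz).any():
        dead = [weights.diseases[i] for i in np.nonzero(~nz)[0]]
        logger.info("zero symptom vector for: %s (similarity set to 0)",
                    ", ".join(dead))
    safe = np.where(nz, norms, 1.0)
    unit = w / safe[:, None]
    S = unit @ unit.T
    np.clip(S, 0.0, 1.0, out=S)
    S = (S + S.T) / 2.0
    S[~nz, :] = 0.0
    S[:, ~nz] = 0.0
    diag = np.where(nz, 1.0, 0.0)
    np.fill_diagonal(S, diag)
    mask = np.outer(nz, nz)
    return SimilarityMatrix(list(weights.diseases), S, role="SS", mask=mask)


def integrate_disease_similarity(SS: SimilarityMatrix | None,
                                 GS: SimilarityMatrix) -> SimilarityMatrix:
    """Integrated disease similarity: symptom-based where present, GIP otherwise.

    ``SS`` may be None, empty, or cover only a subset of GS's diseases; its
    presence mask decides pair by pair.  The result is aligned to GS's labels
    (the association network's diseases), symmetric, with unit diagonal.
    """
    DS = GS.S.copy()
    mask_used = np.zeros_like(DS, dtype=bool)
    if SS is not None and SS.n > 0:
        ss = SS.reindex(GS.labels)
        m = ss.mask if ss.mask is not None else np.ones_like(DS, bool)
        DS[m] = ss.S[m]
        mask_used = m
    np.fill_diagonal(DS, 1.0)
    DS = (DS + DS.T) / 2.0
    return SimilarityMatrix(list(GS.labels), DS, role="DS",
                            meta={"n_symptom_pairs": int(mask_used.sum())})
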