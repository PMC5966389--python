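"""Planted-partition synthetic networks and symptom profiles.

Real microbe-disease catalogues are sparse bipartite networks (mean microbe
degree roughly 1.2-1.7, mean disease degree 6-8) in which groups of diseases
share groups of microbes.  The generator emulates that with a bipartite
planted-partition (block) model: diseases and microbes are split into
``n_blocks`` paired communities and an association is drawn with probability
``p_in`` within a community and ``p_out`` across.  Defaults are scaled to the
genus-level catalogue: 20 diseases x 94 microbes with ~155 expected edges.

Symptom profiles give a ``symptom_coverage`` fraction of diseases Poisson
count vectors concentrated (per ``symptom_signal``) on block-specific symptom
subsets, so same-block diseases have systematically higher cosine similarity
than cross-block pairs — a recoverable planted signal for the integrated
disease similarity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network_data import AssociationNetwork, SymptomProfile

__all__ = ["SyntheticSpec", "generate_network", "generate_symptom_counts",
           "generate", "write_symptom_counts"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic realization (same spec + seed => same data)."""

    n_diseases: int = 20
    n_microbes: int = 94
    n_blocks: int = 4
    p_in: float = 0.28
    p_out: float = 0.016
    symptom_coverage: float = 0.8
    n_symptoms: int = 40
    symptom_signal: float = 0.9
    total_symptom_mass: float = 50.0   # expected co-occurrence counts per disease
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_out < self.p_in <= 1.0):
            raise ValueError("need 0 <= p_out < p_in <= 1")
        if not (0.0 <= self.symptom_coverage <= 1.0):
            raise ValueError("symptom_coverage must be in [0, 1]")
        if not (0.0 <= self.symptom_signal <= 1.0):
            raise ValueError("symptom_signal must be in [0, 1]")
        if min(self.n_diseases, self.n_microbes, self.n_blocks,
               self.n_symptoms) < 1:
            raise ValueError("counts must be positive")
        if self.n_blocks > min(self.n_diseases, self.n_microbes):
            raise ValueError("more blocks than diseases or microbes")


def _blocks(n: int, k: int) -> np.ndarray:
    """Block label per entity, sizes differing by at most one."""
    return np.sort(np.arange(n) % k)


def generate_network(spec: SyntheticSpec) -> AssociationNetwork:
    """Draw a bipartite planted-partition association network."""
    rng = np.random.default_rng(spec.seed)
    db = _blocks(spec.n_diseases, spec.n_blocks)
    mb = _blocks(spec.n_microbes, spec.n_blocks)
    same = db[:, None] == mb[None, :]
    P = np.where(same, spec.p_in, spec.p_out)
    A = (rng.random(P.shape) < P).astype(float)
    diseases = [f"disease_{b}_{i:02d}" for i, b in enumerate(db)]
    microbes = [f"microbe_{b}_{j:03d}" for j, b in enumerate(mb)]
    return AssociationNetwork(diseases, microbes, A)


def generate_symptom_counts(spec: SyntheticSpec,
                            net: AssociationNetwork) -> SymptomProfile:
    """Draw block-structured Poisson symptom counts for a coverage fraction
    of the network's diseases.

    ``symptom_signal`` is the expected fraction of a disease's total
    co-occurrence mass (``total_symptom_mass`` counts on average) landing on
    its own block's symptom subset; the remainder spreads uniformly over the
    other blocks' symptoms.  At ``symptom_signal = 1/n_blocks`` the mass is
    uniform and no structure is planted.
    """
    # second-stream seed so the network draw is unchanged by symptom settings
    rng = np.random.default_rng((int(spec.seed), 1))
    db = _blocks(spec.n_diseases, spec.n_blocks)
    sb = _blocks(spec.n_symptoms, spec.n_blocks)
    n_cov = int(round(spec.symptom_coverage * spec.n_diseases))
    covered = np.sort(rng.choice(spec.n_diseases, size=n_cov, replace=False))
    if n_cov == 0:
        return SymptomProfile(diseases=[], symptoms=[],
                              W=np.zeros((0, 0)))
    n_own = np.array([(sb == b).sum() for b in range(spec.n_blocks)])
    own = n_own[db[covered]].astype(float)          # own-block subset size
    off = float(spec.n_symptoms) - own
    lam_on = spec.symptom_signal * spec.total_symptom_mass / own
    with np.errstate(divide="ignore", invalid="ignore"):
        lam_off = np.where(off > 0,
                           (1.0 - spec.symptom_signal)
                           * spec.total_symptom_mass / np.maximum(off, 1.0),
                           0.0)
    same = db[covered][:, None] == sb[None, :]
    lam = np.where(same, lam_on[:, None], lam_off[:, None])
    W = rng.poisson(lam).astype(float)
    diseases = [net.diseases[i] for i in covered]
    symptoms = [f"symptom_{b}_{m:02d}" for m, b in enumerate(sb)]
    return SymptomProfile(diseases=diseases, symptoms=symptoms, W=W)


def generate(spec: SyntheticSpec) -> tuple[AssociationNetwork, SymptomProfile]:
    """Network plus matching symptom profile from one spec."""
    net = generate_network(spec)
    return net, generate_symptom_counts(spec, net)


def write_symptom_counts(profile: SymptomProfile, path) -> None:
    """Write counts as long-format (disease, symptom, count) TSV, zeros omitted."""
    with open(path, "w") as fh:
        fh.write("#disease\tsymptom\tcount\n")
        for i, d in enumerate(profile.diseases):
            for m, s in enumerate(profile.symptoms):
                c = profile.W[i, m]
                if c > 0:
                    fh.write(f"{d}\t{s}\t{c:g}\n")
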