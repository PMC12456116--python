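"""Scalar mantle-colour phenotype from LAB colour triplets.

Each bird's mantle colour is summarised by CIELAB coordinates: L (luminosity,
0 black to 100 white), a (green negative to red positive) and b (blue
negative to yellow positive). A PCA of the L/a/b matrix yields the axis of
red-to-yellow variation; the component contrasting a against b most strongly
is taken as the phenotypic score for association mapping, with its sign fixed
so that larger scores mean redder birds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MIN_VARIANCE_FRACTION = 0.05  # components below this are not score candidates


@dataclass(frozen=True)
class LabColour:
    sample_id: str
    L: float
    a: float
    b: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.L <= 100.0:
            raise ValueError(f"{self.sample_id}: L={self.L} outside [0, 100]")


@dataclass(frozen=True)
class PcaResult:
    """Loadings are columns of a 3x3 orthonormal matrix (rows: L, a, b)."""

    loadings: np.ndarray
    scores: np.ndarray            # n x 3, centred
    variance_fractions: np.ndarray
    sample_ids: tuple[str, ...]
    mode: str                     # "covariance" | "correlation"


@dataclass(frozen=True)
class PhenotypeScore:
    sample_id: str
    score: float
    pc_index: int
    variance_explained: float


def read_lab(path) -> list[LabColour]:
    df = pd.read_csv(path)
    missing = {"sample_id", "L", "a", "b"} - set(df.columns)
    if missing:
        raise ValueError(f"LAB CSV missing columns: {sorted(missing)}")
    return [LabColour(str(r.sample_id), float(r.L), float(r.a), float(r.b))
            for r in df.itertuples()]


def lab_pca(colours: list[LabColour], mode: str = "covariance") -> PcaResult:
    """PCA of the n x 3 LAB matrix.

    ``covariance`` mode (default) centres each channel; ``correlation`` mode
    additionally scales channels to unit variance. All three components are
    returned with variance fractions summing to 1.
    """
    if len(colours) < 3:
        raise ValueError("PCA needs at least 3 samples")
    if mode not in ("covariance", "correlation"):
        raise ValueError(f"unknown PCA mode {mode!r}")
    X = np.array([[c.L, c.a, c.b] for c in colours], dtype=float)
    Xc = X - X.mean(axis=0)
    if np.allclose(Xc, 0):
        raise ValueError("zero-variance LAB input")
    if mode == "correlation":
        sd = Xc.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    cov = np.cov(Xc, rowvar=False, ddof=1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    # deterministic sign: largest-magnitude loading of each component positive
    for j in range(3):
        k = int(np.argmax(np.abs(eigvecs[:, j])))
        if eigvecs[k, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    fractions = eigvals / eigvals.sum()
    scores = Xc @ eigvecs
    return PcaResult(eigvecs, scores, fractions,
                     tuple(c.sample_id for c in colours), mode)


def phenotype_score(pca: PcaResult, colours: list[LabColour]) -> list[PhenotypeScore]:
    """Select the red-yellow component and return oriented per-sample scores.

    The chosen component maximises |loading_a - loading_b| among components
    explaining at least 5% of variance; its sign is flipped if needed so the
    score correlates positively with the a (redness) channel.
    """
    candidates = [j for j in range(3)
                  if pca.variance_fractions[j] >= MIN_VARIANCE_FRACTION]
    if not candidates:
        candidates = [0]
    contrast = np.abs(pca.loadings[1, :] - pca.loadings[2, :])
    best = max(candidates, key=lambda j: contrast[j])
    ties = [j for j in candidates
            if j != best and np.isclose(contrast[j], contrast[best], atol=1e-12)]
    if ties:
        raise ValueError(f"ambiguous component selection: components {[best] + ties} "
                         f"have equal a-b loading contrast")
    scores = pca.scores[:, best].copy()
    a_vals = np.array([c.a for c in colours], dtype=float)
    corr = np.dot(scores - scores.mean(), a_vals - a_vals.mean())
    if corr < 0:
        scores = -scores
    return [PhenotypeScore(sid, float(s), best, float(pca.variance_fractions[best]))
            for sid, s in zip(pca.sample_ids, scores)]


def score_table(colours: list[LabColour], mode: str = "covariance") -> pd.DataFrame:
    pca = lab_pca(colours, mode=mode)
    scores = phenotype_score(pca, colours)
    return pd.DataFrame({"sample_id": [s.sample_id for s in scores],
                         "score": [s.score for s in scores],
                         "pc_index": [s.pc_index for s in scores],
                         "variance_explained": [s.variance_explained for s in scores]})
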