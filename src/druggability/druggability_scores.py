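"""Druggability scoring: drug-like density (DLID) and SiteMap-style scores.

Two routes to DLID:

* the density form, ``log10(DLLC neighbors / total neighbors) + 1.71``,
  which counts reference pockets with similar (log10 volume, buriedness,
  hydrophobicity) and asks what fraction of them are known to hold a
  drug-like ligand (DLLC); and
* the regression surrogate,
  ``-8.70 + 1.71*log10(volume) + 3.94*buriedness + 2.27*hydrophobicity``,
  used when no reference neighborhood is available.

SiteMap-style scores combine site-point count n (capped at 100),
enclosure e and hydrophilic score p:

* SiteScore = 0.0733*sqrt(n') + 0.6688*e - 0.20*min(p, 1)
* Dscore    = 0.094*sqrt(n')  + 0.60*e  - 0.324*p        (p uncapped)

The default uses sqrt(n'), which is consistent with the calibration that
an average submicromolar site scores ~1.0; ``mode="literal"`` applies the
weights to n' linearly instead (both conventions appear in print).
A pocket is DLID-druggable above 0.5 and site-druggable at SiteScore
>= 0.80.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np

from .errors import NoNeighborsError

__all__ = [
    "ReferencePocketSet",
    "DruggabilityScores",
    "dlid_regression",
    "dlid_density",
    "site_score",
    "dscore",
    "classify",
    "DLID_DRUGGABLE_THRESHOLD",
    "SITESCORE_DRUGGABLE_THRESHOLD",
]

DLID_DRUGGABLE_THRESHOLD = 0.5  # strict: druggable means dlid > 0.5
SITESCORE_DRUGGABLE_THRESHOLD = 0.80  # inclusive
SITE_POINT_CAP = 100
_DLID_LOG_OFFSET = 1.71


@dataclasses.dataclass
class ReferencePocketSet:
    """Labeled reference pockets for the density form of DLID.

    ``entries`` rows are (volume A^3, buriedness, hydrophobicity) and
    ``is_dllc`` marks pockets containing a drug-like ligand. Neighborhoods
    are Euclidean balls of ``neighborhood_radius`` in z-standardized
    (log10 volume, buriedness, hydrophobicity) space; standardization
    statistics come from the reference set itself.
    """

    entries: np.ndarray  # (n, 3): volume, buriedness, hydrophobicity
    is_dllc: np.ndarray  # (n,) bool
    neighborhood_radius: float = 1.0

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=float).reshape(-1, 3)
        self.is_dllc = np.asarray(self.is_dllc, dtype=bool)
        if len(self.entries) == 0:
            raise ValueError("reference set must contain at least one entry")
        if self.neighborhood_radius <= 0:
            raise ValueError("neighborhood_radius must be positive")
        feats = np.column_stack((
            np.log10(self.entries[:, 0]), self.entries[:, 1], self.entries[:, 2]
        ))
        self._mean = feats.mean(axis=0)
        std = feats.std(axis=0)
        self._std = np.where(std > 0, std, 1.0)
        self._feats = (feats - self._mean) / self._std

    def standardize(self, volume: float, buriedness: float, hydrophobicity: float) -> np.ndarray:
        raw = np.array([math.log10(volume), buriedness, hydrophobicity])
        return (raw - self._mean) / self._std


@dataclasses.dataclass
class DruggabilityScores:
    dlid: float
    site_score: float
    dscore: float
    dlid_druggable: bool = False
    site_druggable: bool = False


def dlid_regression(volume: float, buriedness: float, hydrophobicity: float) -> float:
    """Regression surrogate for DLID.

    -8.70 + 1.71*log10(volume) + 3.94*buriedness + 2.27*hydrophobicity
    """
    if volume <= 0:
        raise ValueError(f"volume must be positive, got {volume}")
    if not (0.0 <= buriedness <= 1.0 and 0.0 <= hydrophobicity <= 1.0):
        raise ValueError("buriedness and hydrophobicity must lie in [0, 1]")
    return -8.70 + 1.71 * math.log10(volume) + 3.94 * buriedness + 2.27 * hydrophobicity


def dlid_density(
    volume: float,
    buriedness: float,
    hydrophobicity: float,
    reference: ReferencePocketSet,
) -> float:
    """Density form of DLID: log10(DLLC neighbors / total neighbors) + 1.71.

    Raises :class:`NoNeighborsError` when the neighborhood is empty (the
    regression surrogate is the documented fallback). Returns ``-inf``
    (with a warning) when neighbors exist but none is DLLC.
    """
    q = reference.standardize(volume, buriedness, hydrophobicity)
    d = np.linalg.norm(reference._feats - q, axis=1)
    within = d <= reference.neighborhood_radius
    total = int(within.sum())
    if total == 0:
        raise NoNeighborsError(
            "no reference pockets within the neighborhood radius; "
            "use dlid_regression as a substitute"
        )
    dllc = int(reference.is_dllc[within].sum())
    if dllc == 0:
        warnings.warn("no DLLC pockets among neighbors; DLID is -inf", stacklevel=2)
        return float("-inf")
    return math.log10(dllc / total) + _DLID_LOG_OFFSET


def _site_terms(n: float, e: float, p: float, mode: str) -> tuple[float, float]:
    if n < 0 or e < 0 or p < 0:
        raise ValueError("site-point count, enclosure and hydrophilic score must be >= 0")
    if e > 1.0:
        raise ValueError(f"enclosure is a fraction, got {e}")
    n_capped = min(float(n), float(SITE_POINT_CAP))
    if mode == "sqrt":
        n_term = math.sqrt(n_capped)
    elif mode == "literal":
        n_term = n_capped
    else:
        raise ValueError(f"mode must be 'sqrt' or 'literal', got {mode!r}")
    return n_term, n_capped


def site_score(n: float, e: float, p: float, mode: str = "sqrt") -> float:
    """SiteScore = 0.0733*f(min(n,100)) + 0.6688*e - 0.20*min(p, 1.0)."""
    n_term, _ = _site_terms(n, e, p, mode)
    return 0.0733 * n_term + 0.6688 * e - 0.20 * min(p, 1.0)


def dscore(n: float, e: float, p: float, mode: str = "sqrt") -> float:
    """Dscore = 0.094*f(min(n,100)) + 0.60*e - 0.324*p, with p uncapped."""
    n_term, _ = _site_terms(n, e, p, mode)
    return 0.094 * n_term + 0.60 * e - 0.324 * p


def classify(scores: DruggabilityScores) -> DruggabilityScores:
    """Set the druggability flags: DLID strictly above 0.5; SiteScore >= 0.80."""
    scores.dlid_druggable = scores.dlid > DLID_DRUGGABLE_THRESHOLD
    scores.site_druggable = scores.site_score >= SITESCORE_DRUGGABLE_THRESHOLD
    return scores
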