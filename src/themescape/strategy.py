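"""3D strategic coordinates and the octant taxonomy.

Axes: x (maturity) is the centered, population-standardized keyword
frequency, so mean(x) = 0 by construction; y (influence) is the raw network
strength, so its threshold is the mean strength; z (recency) is the fraction
of the keyword's records falling in the recent window, in [0, 1].

The space is divided into 8 octants by threshold planes (x = 0,
y = mean strength, z = 0.5 by default; z can instead use the mean-z plane).
Boundary equality counts as the >= side.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import CoocNetwork, KeywordStats

__all__ = ["OctantTaxonomy", "OCTANT_LABELS", "compute_axes",
           "default_thresholds", "classify_octant"]

#: (x >= x_thr, y >= y_thr, z >= z_thr) -> octant name. The all-high-but-
#: stale octant carries a package-chosen name (config-overridable); the other
#: seven names follow the standard strategic-diagram taxonomy.
OCTANT_LABELS: dict[tuple[bool, bool, bool], str] = {
    (True, True, True): "Core emerging hotspot",
    (False, True, True): "Potential breakthrough theme",
    (True, False, True): "Peripheral emerging theme",
    (False, False, True): "Exploratory emerging theme",
    (True, False, False): "Peripheral mature theme",
    (False, False, False): "Peripheral obsolete theme",
    (False, True, False): "Immature but declining theme",
    (True, True, False): "Core consolidated theme",
}


@dataclass
class OctantTaxonomy:
    x_threshold: float = 0.0
    y_threshold: float = 0.0
    z_threshold: float = 0.5
    labels: dict[tuple[bool, bool, bool], str] = field(
        default_factory=lambda: dict(OCTANT_LABELS)
    )

    def __post_init__(self) -> None:
        if set(self.labels) != set(OCTANT_LABELS):
            raise ValueError("labels must cover all 8 sign-triples exactly")


def compute_axes(
    stats: list[KeywordStats],
    net: CoocNetwork,
    recent_window: int = 5,
    reference_year: int | None = None,
) -> pd.DataFrame:
    """Per-keyword strategic coordinates over the network's keywords.

    ``z`` uses each keyword's precomputed ``recent_fraction``
    (:func:`themescape.network.keyword_frequencies` takes ``recent_window``
    and ``reference_year``; they are accepted here for interface symmetry and
    must match what the stats were built with).
    """
    by_kw = {s.keyword: s for s in stats}
    keywords = [k for k in net.nodes if k in by_kw]
    if not keywords:
        raise ValueError("stats and network share no keywords")
    freqs = np.array([by_kw[k].frequency for k in keywords], dtype=float)
    sd = freqs.std()  # population sd
    if sd == 0:
        warnings.warn("all keyword frequencies equal; maturity axis set to 0",
                      stacklevel=2)
        x = np.zeros(len(freqs))
    else:
        x = (freqs - freqs.mean()) / sd
    df = pd.DataFrame(
        {
            "keyword": keywords,
            "x": x,
            "y": [net.strength(k) for k in keywords],
            "z": [by_kw[k].recent_fraction for k in keywords],
        }
    )
    return df


def default_thresholds(coords: pd.DataFrame, z_mode: str = "fixed") -> OctantTaxonomy:
    """Threshold planes: x = 0, y = mean strength, z = 0.5 (``z_mode="fixed"``,
    the reference-point convention) or z = mean z (``z_mode="mean"``)."""
    if z_mode not in ("fixed", "mean"):
        raise ValueError("z_mode must be 'fixed' or 'mean'")
    return OctantTaxonomy(
        x_threshold=0.0,
        y_threshold=float(coords["y"].mean()),
        z_threshold=0.5 if z_mode == "fixed" else float(coords["z"].mean()),
    )


def classify_octant(coords: pd.DataFrame, taxonomy: OctantTaxonomy) -> pd.DataFrame:
    """Assign every keyword its octant label (boundary equality counts as >=)."""
    out = coords.copy()
    out["octant"] = [
        taxonomy.labels[
            (
                x >= taxonomy.x_threshold,
                y >= taxonomy.y_threshold,
                z >= taxonomy.z_threshold,
            )
        ]
        for x, y, z in zip(out["x"], out["y"], out["z"])
    ]
    return out
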