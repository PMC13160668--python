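"""Loaders for the packaged reference tables.

Two small plain-text fixtures ship with the package, transcribed from the
published per-keyword metrics of a PubMed social-media-mining corpus
(n=189 analyzed records, 78 retained keywords):

* ``keyword_table`` — per-keyword cluster, record frequency, co-occurrence
  degree, network strength, centroid distance, and strategic octant label.
* ``coupling_table`` — the top 5 intercluster pairs with their cross-cluster
  strengths and top-5 bridging keyword contributions. The source reports two
  inconsistent strengths for the pairs (2,4) and (2,6) — its table and its
  body text swap 7.216 and 6.967 — so both readings are stored
  (``cross_cluster_strength`` follows the table,
  ``cross_cluster_strength_text`` the body text).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_keyword_table", "load_coupling_table"]


def _read(name: str) -> pd.DataFrame:
    with resources.files("themescape.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_keyword_table() -> pd.DataFrame:
    """The 78-keyword reference table (clusters, metrics, octant labels)."""
    df = _read("keyword_table.csv")
    if df["keyword"].duplicated().any():
        raise ValueError("corrupt fixture: duplicate keywords")
    return df


def load_coupling_table(validate: bool = True) -> pd.DataFrame:
    """Top intercluster pairs with bridging-keyword contributions.

    With ``validate=True`` (default) a dual-attribution sanity check is
    applied: for every pair the stored top-5 contributions must not exceed
    twice the pair strength (each cross edge is credited to both endpoint
    keywords, so per-pair contributions sum to exactly 2x the strength).
    """
    df = _read("coupling_table.csv")
    if validate:
        for (a, b), grp in df.groupby(["cluster_a", "cluster_b"]):
            strength = grp["cross_cluster_strength"].iloc[0]
            if grp["contribution"].sum() > 2.0 * strength + 1e-9:
                raise ValueError(
                    f"fixture pair ({a},{b}): top-5 contributions exceed "
                    f"2x pair strength"
                )
    return df
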