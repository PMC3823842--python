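"""Hub identification from integrated betweenness centrality.

Each subject's integrated nodal betweenness vector aBC is first
normalized by its own mean over the N nodes (so every subject's vector
averages to 1 and subjects with denser paths do not dominate); the
normalized vectors are then averaged over subjects.  A region is a hub
of a condition's group network when its group-level normalized value
exceeds the across-region mean by more than one sample standard
deviation.

``mode="global"`` offers a sensitivity variant that divides all vectors
by the grand mean over subjects and nodes instead of subject-wise means.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .atlas import RegionAtlas


def normalize_betweenness(abc: np.ndarray, mode: str = "subject") -> np.ndarray:
    """Group-level normalized betweenness from per-subject aBC vectors.

    Parameters
    ----------
    abc
        M x N array (subjects by regions) or a single length-N vector.
    mode
        ``"subject"`` (default): divide each subject's vector by its own
        mean; ``"global"``: divide everything by the grand mean.
    """
    X = np.atleast_2d(np.asarray(abc, dtype=float))
    if mode == "subject":
        means = X.mean(axis=1, keepdims=True)
        if (means == 0).any():
            k = int(np.flatnonzero(means[:, 0] == 0)[0])
            raise ValueError(f"zero-mean betweenness vector for subject index {k}")
        X = X / means
    elif mode == "global":
        g = X.mean()
        if g == 0:
            raise ValueError("zero grand-mean betweenness")
        X = X / g
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return X.mean(axis=0)


def identify_hubs(
    normalized: np.ndarray, atlas: RegionAtlas, condition: str | None = None
) -> pd.DataFrame:
    """Flag regions whose normalized betweenness exceeds mean + 1 SD.

    The threshold uses the sample SD (N-1 denominator) over regions of
    the group-level vector; the flag is strict (> threshold).  Returns a
    DataFrame in atlas order with columns region, classification,
    normalized_bc, is_hub (plus condition when given).
    """
    v = np.asarray(normalized, dtype=float)
    n = len(v)
    if n < 3:
        raise ValueError("hub criterion needs at least 3 regions")
    if n != atlas.n_regions:
        raise ValueError(f"{n} values for an atlas of {atlas.n_regions} regions")
    threshold = v.mean() + v.std(ddof=1)
    out = pd.DataFrame(
        {
            "region": atlas.labels,
            "classification": atlas.table["classification"].tolist(),
            "normalized_bc": v,
            "is_hub": v > threshold,
        }
    )
    if condition is not None:
        out.insert(0, "condition", condition)
    return out


def hub_table(
    normalized_by_condition: dict[str, np.ndarray], atlas: RegionAtlas
) -> pd.DataFrame:
    """Hub report across conditions: per-condition values and flags plus a
    shared-hub marker, restricted to regions that are a hub in at least
    one condition (the structure of a per-region hub summary table)."""
    conds = list(normalized_by_condition)
    parts = {c: identify_hubs(normalized_by_condition[c], atlas, c) for c in conds}
    out = pd.DataFrame(
        {
            "region": atlas.labels,
            "classification": atlas.table["classification"].tolist(),
        }
    )
    for c in conds:
        out[f"normalized_bc_{c}"] = parts[c]["normalized_bc"].round(2)
        out[f"is_hub_{c}"] = parts[c]["is_hub"]
    flags = np.column_stack([parts[c]["is_hub"].to_numpy() for c in conds])
    out["shared_hub"] = flags.all(axis=1)
    return out[flags.any(axis=1)].reset_index(drop=True)
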