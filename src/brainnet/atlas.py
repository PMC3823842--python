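"""Region atlases and labeled matrix I/O.

The network pipeline identifies nodes by rows of a region atlas: a small
table with a contiguous 1-based index, a region name, an abbreviation, a
hemisphere code and a cortical classification.  The bundled 90-region AAL
(automated anatomical labeling) table pairs each of 45 anatomical regions
across hemispheres, odd indices on the left and even on the right; any
other atlas of N >= 3 regions in the same format is accepted.

Matrices (correlation or binary adjacency) are stored as square
tab-separated text with a header row of node labels such as ``PreCG.L``.
Values are written at full double precision so that a write/read
round-trip is bit-exact.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HEMISPHERES = ("left", "right", "none")
CLASSIFICATIONS = ("primary", "association", "paralimbic", "subcortical", "unstated")

_HEMI_SUFFIX = {"left": ".L", "right": ".R", "none": ""}

#: Maximum |M - M.T| accepted silently by :class:`LabeledMatrix`.
SYMMETRY_TOL = 1e-10
#: Maximum |M - M.T| that :func:`read_matrix` repairs by averaging.
READ_ASYMMETRY_TOL = 1e-8


class AtlasError(ValueError):
    """Raised for malformed atlas tables or matrix files."""


@dataclass(frozen=True)
class RegionAtlas:
    """Validated table of network nodes.

    Parameters
    ----------
    table
        DataFrame with columns ``index`` (1-based, contiguous), ``name``,
        ``abbreviation``, ``hemisphere`` and ``classification``.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = ["index", "name", "abbreviation", "hemisphere", "classification"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise AtlasError(f"atlas table missing columns: {missing}")
        t = self.table.reset_index(drop=True)
        object.__setattr__(self, "table", t)
        idx = t["index"].to_numpy()
        n = len(t)
        if n < 2:
            raise AtlasError("atlas must contain at least 2 regions")
        if len(set(idx)) != n:
            dup = t[t["index"].duplicated()].iloc[0]
            raise AtlasError(f"duplicate region_index {dup['index']} (row {dup.name})")
        if sorted(idx) != list(range(1, n + 1)):
            bad = sorted(set(range(1, n + 1)) - set(idx))
            raise AtlasError(f"non-contiguous region_index: expected 1..{n}, missing {bad}")
        for col, allowed in (("hemisphere", HEMISPHERES), ("classification", CLASSIFICATIONS)):
            bad_rows = t[~t[col].isin(allowed)]
            if len(bad_rows):
                r = bad_rows.iloc[0]
                raise AtlasError(
                    f"unknown {col} {r[col]!r} for region_index {r['index']}"
                )
        pairs = list(zip(t["abbreviation"], t["hemisphere"]))
        if len(set(pairs)) != n:
            seen: set = set()
            for p in pairs:
                if p in seen:
                    raise AtlasError(f"duplicate (abbreviation, hemisphere) pair {p}")
                seen.add(p)
        # canonical row order = region_index order
        object.__setattr__(
            self, "table", t.sort_values("index").reset_index(drop=True)
        )

    @property
    def n_regions(self) -> int:
        return len(self.table)

    @property
    def labels(self) -> list[str]:
        """Node labels, abbreviation plus hemisphere suffix (``IFGtriang.L``)."""
        return [
            f"{a}{_HEMI_SUFFIX[h]}"
            for a, h in zip(self.table["abbreviation"], self.table["hemisphere"])
        ]

    def classification_of(self, label: str) -> str:
        i = self.labels.index(label)
        return str(self.table["classification"].iloc[i])


def load_atlas(path) -> RegionAtlas:
    """Read a delimited atlas table and validate it."""
    t = pd.read_csv(path, sep="\t", dtype={"index": int})
    return RegionAtlas(t)


def default_atlas() -> RegionAtlas:
    """The bundled 90-region AAL atlas (45 regions per hemisphere)."""
    ref = importlib.resources.files("brainnet") / "data" / "aal90.tsv"
    with importlib.resources.as_file(ref) as p:
        return load_atlas(p)


def generic_atlas(n: int) -> RegionAtlas:
    """A featureless atlas of ``n`` regions, for synthetic cohorts that do
    not correspond to an anatomical parcellation."""
    t = pd.DataFrame(
        {
            "index": np.arange(1, n + 1),
            "name": [f"Region {i}" for i in range(1, n + 1)],
            "abbreviation": [f"R{i:03d}" for i in range(1, n + 1)],
            "hemisphere": ["none"] * n,
            "classification": ["unstated"] * n,
        }
    )
    return RegionAtlas(t)


@dataclass
class LabeledMatrix:
    """Square symmetric matrix with atlas node labels.

    ``kind`` is ``"correlation"`` for Pearson connectivity matrices and
    ``"adjacency"`` for binarized networks.
    """

    values: np.ndarray
    labels: list[str]
    kind: str = "correlation"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise AtlasError(f"matrix must be square, got shape {v.shape}")
        if len(self.labels) != v.shape[0]:
            raise AtlasError(
                f"{len(self.labels)} labels for a {v.shape[0]}x{v.shape[0]} matrix"
            )
        if self.kind not in ("correlation", "adjacency"):
            raise AtlasError(f"unknown matrix kind {self.kind!r}")
        asym = np.nanmax(np.abs(v - v.T)) if v.size else 0.0
        if asym > SYMMETRY_TOL:
            raise AtlasError(f"matrix asymmetry {asym:g} exceeds {SYMMETRY_TOL:g}")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]


def read_matrix(path, atlas: RegionAtlas) -> LabeledMatrix:
    """Read a square TSV matrix, with or without a header row of labels.

    Small numerical asymmetry (<= 1e-8) is repaired by averaging with the
    transpose; larger asymmetry is an error, as is any dimension mismatch
    with the atlas.
    """
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
        tokens = first.rstrip("\n").split("\t")
        has_header = False
        try:
            [float(tok) for tok in tokens if tok != ""]
        except ValueError:
            has_header = True
        rows = [] if has_header else [tokens]
        rows.extend(line.rstrip("\n").split("\t") for line in fh if line.strip())
    n = atlas.n_regions
    if len(rows) != n or any(len(r) != n for r in rows):
        raise AtlasError(
            f"matrix in {path} is {len(rows)}x{len(rows[0]) if rows else 0}, "
            f"atlas has {n} regions"
        )
    try:
        m = np.array([[float(x) for x in r] for r in rows])
    except ValueError as e:
        raise AtlasError(f"non-numeric cell in {path}: {e}") from None
    asym = np.max(np.abs(m - m.T))
    if asym > READ_ASYMMETRY_TOL:
        raise AtlasError(f"asymmetry {asym:g} in {path} exceeds {READ_ASYMMETRY_TOL:g}")
    m = (m + m.T) / 2.0
    vals = np.unique(m)
    kind = "adjacency" if np.all(np.isin(vals, (0.0, 1.0))) else "correlation"
    return LabeledMatrix(m, atlas.labels, kind=kind)


def write_matrix(matrix: LabeledMatrix, path) -> str:
    """Write a LabeledMatrix as TSV with a header row of labels.

    Floats are serialized with ``%.17g`` so re-reading reproduces the
    values bit-for-bit.  NaN values are rejected.
    """
    if np.isnan(matrix.values).any():
        raise AtlasError("matrix contains NaN; refusing to write")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(matrix.labels) + "\n")
        for row in matrix.values:
            fh.write("\t".join(f"{x:.17g}" for x in row) + "\n")
    return str(path)
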