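"""Cortical parcellation frame, hemisphere pairing, and a-priori regions of interest.

Every table and matrix in the pipeline is indexed by an ordered parcellation
scheme.  The packaged default is the 360-region surface-based HCP-MMP cortical
atlas (180 region labels, each present once per hemisphere).  Reduced schemes
for desk-scale work are built by subsetting base labels; hemisphere pairing is
always preserved so that laterality operations stay defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import pandas as pd

HEMISPHERES = ("L", "R")


@dataclass(frozen=True)
class RegionInfo:
    """One cortical region: position in atlas order, short label, hemisphere."""

    index: int
    label: str
    hemisphere: str
    group: str = "other"

    @property
    def full_label(self) -> str:
        """Unique label including the hemisphere suffix, e.g. ``V1_L``."""
        return f"{self.label}_{self.hemisphere}"


class ParcellationScheme:
    """Ordered collection of paired cortical regions.

    Parameters
    ----------
    regions
        Regions in atlas order.  Labels must be unique within a hemisphere and
        every base label must appear in both hemispheres.
    """

    def __init__(self, regions: Sequence[RegionInfo]):
        regions = list(regions)
        by_hemi: dict[str, list[str]] = {h: [] for h in HEMISPHERES}
        for r in regions:
            if r.hemisphere not in HEMISPHERES:
                raise ValueError(f"unknown hemisphere code {r.hemisphere!r} for {r.label!r}")
            if r.label in by_hemi[r.hemisphere]:
                raise ValueError(f"duplicate label {r.label!r} in hemisphere {r.hemisphere}")
            by_hemi[r.hemisphere].append(r.label)
        if set(by_hemi["L"]) != set(by_hemi["R"]):
            odd = set(by_hemi["L"]).symmetric_difference(by_hemi["R"])
            raise ValueError(f"labels not paired across hemispheres: {sorted(odd)}")
        self.regions: list[RegionInfo] = regions
        self._pos = {r.full_label: i for i, r in enumerate(regions)}

    # -- basic shape -------------------------------------------------------

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def n_per_hemisphere(self) -> int:
        return len(self.regions) // 2

    @property
    def column_labels(self) -> list[str]:
        """Full (hemisphere-qualified) labels in atlas order; headers of every table."""
        return [r.full_label for r in self.regions]

    @property
    def base_labels(self) -> list[str]:
        """Base labels in left-hemisphere atlas order (one per region pair)."""
        return [r.label for r in self.regions if r.hemisphere == "L"]

    # -- lookup ------------------------------------------------------------

    def position(self, label: str, hemisphere: str) -> int:
        """Column position of a (label, hemisphere) region."""
        key = f"{label}_{hemisphere}"
        if key not in self._pos:
            raise KeyError(f"region {label!r} ({hemisphere}) not in scheme")
        return self._pos[key]

    def hemisphere_positions(self, hemisphere: str) -> list[int]:
        return [i for i, r in enumerate(self.regions) if r.hemisphere == hemisphere]

    def pairs(self) -> list[tuple[str, int, int]]:
        """(base label, left position, right position) for every region pair."""
        return [(lab, self.position(lab, "L"), self.position(lab, "R"))
                for lab in self.base_labels]

    def subset(self, base_labels: Iterable[str]) -> "ParcellationScheme":
        """Reduced scheme keeping the given base labels (both hemispheres)."""
        keep = list(base_labels)
        missing = [b for b in keep if f"{b}_L" not in self._pos]
        if missing:
            raise KeyError(f"labels not in scheme: {missing}")
        regions = [r for r in self.regions if r.label in set(keep)]
        return ParcellationScheme(
            [RegionInfo(i + 1, r.label, r.hemisphere, r.group)
             for i, r in enumerate(regions)]
        )

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"index": [r.index for r in self.regions],
             "label": [r.label for r in self.regions],
             "hemisphere": [r.hemisphere for r in self.regions],
             "group": [r.group for r in self.regions]}
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"ParcellationScheme(n_regions={self.n_regions})"


def load_parcellation(table: pd.DataFrame | str) -> ParcellationScheme:
    """Build a scheme from a region metadata table (or a TSV path).

    The table needs ``index``, ``label`` and ``hemisphere`` columns; a ``group``
    column is optional.  Rows are taken in ``index`` order.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, sep="\t", dtype={"label": str})
    required = {"index", "label", "hemisphere"}
    missing = required.difference(table.columns)
    if missing:
        raise ValueError(f"region table is missing columns: {sorted(missing)}")
    table = table.sort_values("index", kind="stable")
    regions = [
        RegionInfo(int(row["index"]), str(row["label"]), str(row["hemisphere"]),
                   str(row.get("group", "other")))
        for _, row in table.iterrows()
    ]
    return ParcellationScheme(regions)


def default_scheme() -> ParcellationScheme:
    """The packaged 360-region HCP-MMP scheme (180 labels per hemisphere)."""
    with resources.as_file(resources.files("hopfec.data") / "hcpmmp360.tsv") as p:
        return load_parcellation(str(p))


# ---------------------------------------------------------------------------
# A-priori regions of interest
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ROISet:
    """Named set of region labels, optionally restricted to one hemisphere."""

    name: str
    labels: tuple[str, ...]
    hemisphere_scope: str = "both"

    def resolve(self, scheme: ParcellationScheme) -> list[int]:
        """Column positions of every member region under the scope."""
        hemis = HEMISPHERES if self.hemisphere_scope == "both" else (self.hemisphere_scope,)
        positions = []
        for lab in self.labels:
            for h in hemis:
                positions.append(scheme.position(lab, h))
        if not positions:
            raise ValueError(f"ROI {self.name!r} resolves to no regions")
        return positions

    def scoped(self, hemisphere_scope: str) -> "ROISet":
        return ROISet(self.name, self.labels, hemisphere_scope)


# The a-priori hypothesis sets: the ventromedial-visual/parahippocampal scene
# stream, the anterior-temporal semantic system, Broca's area, the medial
# reward system (vmPFC / pregenual ACC / medial OFC), and intraparietal regions.
_ROI_LABELS = {
    "scene": ("VMV1", "VMV2", "VMV3", "VVC", "PHA1", "PHA2", "PHA3"),
    "semantic": ("STGa", "STSda", "STSdp", "STSvp", "TGd", "TGv", "PSL"),
    "broca": ("44", "45", "47l"),
    "reward": ("d32", "p24", "pOFC", "s32", "10d", "10pp", "11l", "a10p", "OFC", "p10p"),
    "intraparietal": ("LIPv", "MIP", "VIP"),
}


def apriori_roi_sets(scheme: ParcellationScheme) -> dict[str, ROISet]:
    """The packaged a-priori ROI sets, checked against the active scheme."""
    sets = {}
    for name, labels in _ROI_LABELS.items():
        for lab in labels:
            if f"{lab}_L" not in scheme._pos:
                raise KeyError(f"ROI {name!r}: label {lab!r} absent from scheme")
        sets[name] = ROISet(name, labels)
    return sets
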