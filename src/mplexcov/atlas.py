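"""Cortical parcellation atlases.

An atlas fixes the node set of every network in an analysis: region
identifiers are hemisphere-prefixed (``lh-entorhinal``) and their order is
canonical — all matrices derived from a cohort use this order, whatever the
column order of the input files.

Two parcellations ship with the package: the 68-region Desikan-Killiany
gyral atlas (34 regions per hemisphere, with a lobe tag per region) and the
148-region Destrieux gyral/sulcal atlas. Arbitrary region lists are also
accepted, so atlas size is a free parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources


@dataclass(frozen=True)
class RoiAtlas:
    """An ordered, immutable list of region-of-interest identifiers.

    Parameters
    ----------
    name
        Text label for the parcellation (e.g. ``"dk68"``).
    regions
        Ordered region identifiers; the order is canonical for all
        downstream matrices.
    lobes
        Optional map region -> lobe tag, used only for reporting.
    """

    name: str
    regions: tuple[str, ...]
    lobes: dict[str, str] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if len(set(self.regions)) != len(self.regions):
            dupes = sorted({r for r in self.regions if list(self.regions).count(r) > 1})
            raise ValueError(f"duplicate region identifiers in atlas: {dupes}")
        if not self.regions:
            raise ValueError("atlas must contain at least one region")

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def hemisphere(self, region: str) -> str:
        """Return 'lh'/'rh' for hemisphere-prefixed identifiers, else ''."""
        for hemi in ("lh", "rh"):
            if region.startswith(hemi + "-") or region.startswith(hemi + "_"):
                return hemi
        return ""

    def lobe(self, region: str) -> str:
        if self.lobes is None:
            return ""
        return self.lobes.get(region, "")

    def index_of(self, region: str) -> int:
        return self.regions.index(region)


def _data_text(fname: str) -> str:
    return resources.files("mplexcov.data").joinpath(fname).read_text()


def load_atlas(name: str = "dk68") -> RoiAtlas:
    """Load a bundled atlas by name (``"dk68"`` or ``"destrieux148"``)."""
    if name == "dk68":
        lines = _data_text("dk68.tsv").strip().splitlines()[1:]
        pairs = [ln.split("\t") for ln in lines]
        return RoiAtlas(
            name="dk68",
            regions=tuple(r for r, _ in pairs),
            lobes={r: lobe for r, lobe in pairs},
        )
    if name == "destrieux148":
        regions = tuple(_data_text("destrieux148.txt").split())
        return RoiAtlas(name="destrieux148", regions=regions)
    raise ValueError(f"unknown atlas {name!r}; bundled: 'dk68', 'destrieux148'")


def synthetic_atlas(n_regions: int, name: str = "synthetic") -> RoiAtlas:
    """A generic atlas of ``n_regions`` placeholder ROIs, split lh/rh.

    Used by the cohort simulator when no real parcellation is requested.
    """
    half = n_regions // 2
    regions = tuple(
        f"{'lh' if i < half else 'rh'}-roi{i:03d}" for i in range(n_regions)
    )
    return RoiAtlas(name=name, regions=regions)
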