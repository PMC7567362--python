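"""Packaged ROI registry: 48 white-matter tracts and 82 gray-matter regions.

The registry fixes the row/column order of every functional correlation
matrix (FCM) produced by the pipeline.  White matter follows the Eve atlas
parcellation (21 deep tracts per hemisphere plus 6 commissural/midline
tracts); gray matter is 41 Brodmann areas per hemisphere.  Abbreviations
carry an ``l``/``r`` suffix for lateralized regions (e.g. ``CSTl``,
``BA17r``) and no suffix for midline tracts (e.g. ``FX``, ``SCC``).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = ["RoiEntry", "RoiRegistry", "load_registry", "validate_registry"]

# hemisphere bookkeeping the packaged registry must satisfy
_EXPECTED = {
    "WM": {"left": 21, "right": 21, "midline": 6},
    "GM": {"left": 41, "right": 41, "midline": 0},
}


@dataclass(frozen=True)
class RoiEntry:
    abbreviation: str
    name: str
    tissue: str  # "WM" or "GM"
    hemisphere: str  # "left", "right" or "midline"
    label: int  # integer label value in the atlas volume


class RoiRegistry:
    """Ordered collection of ROI entries with WM/GM index helpers."""

    def __init__(self, entries: list[RoiEntry]):
        abbrs = [e.abbreviation for e in entries]
        dups = sorted({a for a in abbrs if abbrs.count(a) > 1})
        if dups:
            raise ValueError(f"duplicate ROI abbreviations: {', '.join(dups)}")
        self.entries = list(entries)
        self._index = {e.abbreviation: i for i, e in enumerate(self.entries)}

    # -- ordered views -------------------------------------------------
    @property
    def abbreviations(self) -> list[str]:
        return [e.abbreviation for e in self.entries]

    @property
    def wm(self) -> list[RoiEntry]:
        return [e for e in self.entries if e.tissue == "WM"]

    @property
    def gm(self) -> list[RoiEntry]:
        return [e for e in self.entries if e.tissue == "GM"]

    @property
    def wm_abbreviations(self) -> list[str]:
        return [e.abbreviation for e in self.wm]

    @property
    def gm_abbreviations(self) -> list[str]:
        return [e.abbreviation for e in self.gm]

    def index_of(self, abbreviation: str) -> int:
        return self._index[abbreviation]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def subset(self, abbreviations: list[str]) -> "RoiRegistry":
        """Registry restricted to the given abbreviations, in registry order."""
        keep = set(abbreviations)
        missing = keep - set(self._index)
        if missing:
            raise KeyError(f"unknown ROI abbreviations: {sorted(missing)}")
        return RoiRegistry([e for e in self.entries if e.abbreviation in keep])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([e.__dict__ for e in self.entries])


def _read_registry_csv(path) -> RoiRegistry:
    df = pd.read_csv(path)
    required = {"abbreviation", "name", "tissue", "hemisphere", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"registry CSV missing columns: {sorted(missing)}")
    entries = [
        RoiEntry(str(r.abbreviation), str(r.name), str(r.tissue),
                 str(r.hemisphere), int(r.label))
        for r in df.itertuples()
    ]
    return RoiRegistry(entries)


def load_registry(path: str | Path | None = None) -> RoiRegistry:
    """Load the packaged full registry, or a registry CSV from ``path``."""
    if path is not None:
        return _read_registry_csv(path)
    with resources.files("wmfc").joinpath("data/roi_registry.csv").open() as f:
        return _read_registry_csv(f)


def validate_registry(path: str | Path | None = None) -> RoiRegistry:
    """Load a registry and verify the packaged-cohort counts.

    Requires exactly 48 WM ROIs (21 left + 21 right + 6 midline) and 82 GM
    ROIs (41 left + 41 right).  On a count mismatch the error names the
    abbreviations missing relative to the packaged registry (or, for
    surpluses, the unexpected ones).
    """
    reg = load_registry(path)
    packaged = load_registry() if path is not None else reg
    for tissue, by_hemi in _EXPECTED.items():
        have = [e for e in reg.entries if e.tissue == tissue]
        want_total = sum(by_hemi.values())
        if len(have) != want_total:
            expected = {e.abbreviation for e in packaged.entries if e.tissue == tissue}
            got = {e.abbreviation for e in have}
            missing = sorted(expected - got)
            extra = sorted(got - expected)
            parts = [f"{tissue}: expected {want_total} ROIs, found {len(have)}"]
            if missing:
                parts.append("missing: " + ", ".join(missing))
            if extra:
                parts.append("unexpected: " + ", ".join(extra))
            raise ValueError("; ".join(parts))
        for hemi, count in by_hemi.items():
            n = sum(1 for e in have if e.hemisphere == hemi)
            if n != count:
                raise ValueError(
                    f"{tissue}/{hemi}: expected {count} ROIs, found {n}"
                )
    return reg
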