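"""Atlas label bookkeeping.

Ships a Hammersmith-style 83-region label fixture (synthetic name list;
all algorithms treat labels as opaque strings, so any parcellation and
region count works).  The cerebellar labels form the reference-region
set used for SUVr normalization during image extraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

__all__ = ["AtlasLabels", "load_default_atlas", "default_region_labels"]


@dataclass(frozen=True)
class AtlasLabels:
    """Integer label ids mapped to region names, plus the reference set."""

    names: dict[int, str]
    reference_ids: frozenset[int]

    def __post_init__(self) -> None:
        if not self.reference_ids <= set(self.names):
            raise ValueError("reference ids must be a subset of atlas ids")

    @property
    def analysis_ids(self) -> list[int]:
        return [i for i in sorted(self.names) if i not in self.reference_ids]

    @property
    def analysis_names(self) -> list[str]:
        return [self.names[i] for i in self.analysis_ids]

    @classmethod
    def from_text(cls, text: str) -> "AtlasLabels":
        names: dict[int, str] = {}
        reference: set[int] = set()
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"atlas line {lineno}: expected 'id<TAB>name<TAB>role'")
            rid = int(parts[0])
            if rid in names:
                raise ValueError(f"atlas line {lineno}: duplicate id {rid}")
            names[rid] = parts[1]
            if parts[2] == "reference":
                reference.add(rid)
            elif parts[2] != "analysis":
                raise ValueError(f"atlas line {lineno}: unknown role {parts[2]!r}")
        return cls(names=names, reference_ids=frozenset(reference))


def load_default_atlas() -> AtlasLabels:
    """Load the packaged 83-region Hammersmith-style label set."""
    text = (
        resources.files("netpert.data").joinpath("hammersmith_83.txt").read_text("utf-8")
    )
    return AtlasLabels.from_text(text)


def default_region_labels(n_regions: int) -> list[str]:
    """First ``n_regions`` analysis labels, padded with generic names if needed."""
    names = load_default_atlas().analysis_names
    if n_regions <= len(names):
        return names[:n_regions]
    extra = [f"region_{i + 1:03d}" for i in range(len(names), n_regions)]
    return names + extra
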