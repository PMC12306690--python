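"""TOML configuration: sections map onto the module config dataclasses.

Recognised sections: [preprocess], [regions], [biomarkers], [biomarkers.cre].
Unknown keys raise, so typos fail loudly rather than silently using defaults.
"""

from __future__ import annotations

import tomllib
from dataclasses import fields, replace
from pathlib import Path

from .biomarkers import BiomarkerConfig, CREConfig
from .preprocess import PreprocessConfig
from .regions import RegionConfig

__all__ = ["PipelineConfig", "load_config"]


class PipelineConfig:
    """Bundle of all tunable configuration used by the CLI."""

    def __init__(
        self,
        preprocess: PreprocessConfig | None = None,
        regions: RegionConfig | None = None,
        biomarkers: BiomarkerConfig | None = None,
    ):
        self.preprocess = preprocess or PreprocessConfig()
        self.regions = regions or RegionConfig()
        self.biomarkers = biomarkers or BiomarkerConfig(regions=self.regions)


def _apply(dc, section: dict, where: str):
    valid = {f.name for f in fields(dc)}
    unknown = set(section) - valid
    if unknown:
        raise KeyError(f"unknown key(s) {sorted(unknown)} in [{where}]")
    return replace(dc, **section)


def load_config(path) -> PipelineConfig:
    data = tomllib.loads(Path(path).read_text())
    pre = _apply(PreprocessConfig(), data.get("preprocess", {}), "preprocess")
    reg = _apply(RegionConfig(), data.get("regions", {}), "regions")
    bio_section = dict(data.get("biomarkers", {}))
    cre = _apply(CREConfig(), bio_section.pop("cre", {}), "biomarkers.cre")
    bio = _apply(
        BiomarkerConfig(cre=cre, regions=reg), bio_section, "biomarkers"
    )
    return PipelineConfig(preprocess=pre, regions=reg, biomarkers=bio)
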