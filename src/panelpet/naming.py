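"""Scanner configuration names: ``CS<cross-section>_L<length>_CTR<ctr>``
with optional ``_pitch<p>`` token and ``submod`` suffix for
submodule-level readout (e.g. ``CS3_L10_CTR75``, ``CS1.5_L10_CTR75_pitch2``,
``CS3_L10_CTR75submod``)."""

from __future__ import annotations

import re
from dataclasses import dataclass

from .coincidence import CoincidencePolicy, flat_panel_policy, reference_policy
from .geometry import (
    CrystalSpec,
    ReadoutLevel,
    ScannerGeometry,
    build_flat_panel,
    build_reference_ring,
)

_NAME_RE = re.compile(
    r"^CS(?P<cs>\d+(?:\.\d+)?)"
    r"_L(?P<length>\d+(?:\.\d+)?)"
    r"_CTR(?P<ctr>\d+(?:\.\d+)?)"
    r"(?:_pitch(?P<pitch>\d+(?:\.\d+)?))?"
    r"(?P<submod>submod)?$"
)

GRAMMAR = "CS<cross-section>_L<length>_CTR<ctr>[_pitch<p>][submod]"


class NameParseError(ValueError):
    pass


@dataclass(frozen=True)
class ScannerConfigName:
    cross_section_mm: float
    length_mm: float
    ctr_ps: float
    pitch_mm: float = 3.0
    readout: ReadoutLevel = ReadoutLevel.CRYSTAL

    def format(self) -> str:
        def num(x):
            return f"{x:g}"

        s = f"CS{num(self.cross_section_mm)}_L{num(self.length_mm)}_CTR{num(self.ctr_ps)}"
        if self.pitch_mm != 3.0:
            s += f"_pitch{num(self.pitch_mm)}"
        if self.readout == ReadoutLevel.SUBMODULE:
            s += "submod"
        return s


def parse_config_name(text: str) -> ScannerConfigName:
    m = _NAME_RE.match(text.strip())
    if not m:
        raise NameParseError(f"cannot parse {text!r}; expected grammar {GRAMMAR}")
    return ScannerConfigName(
        cross_section_mm=float(m.group("cs")),
        length_mm=float(m.group("length")),
        ctr_ps=float(m.group("ctr")),
        pitch_mm=float(m.group("pitch")) if m.group("pitch") else 3.0,
        readout=ReadoutLevel.SUBMODULE if m.group("submod") else ReadoutLevel.CRYSTAL,
    )


def build_scanner(name: str):
    """(geometry, policy) for a configuration name or ``reference``."""
    if name.strip().lower() in ("reference", "reference scanner", "ref"):
        return build_reference_ring(), reference_policy()
    cfg = parse_config_name(name)
    geom = build_flat_panel(
        CrystalSpec(
            cross_section=cfg.cross_section_mm,
            length=cfg.length_mm,
            pitch=cfg.pitch_mm,
        )
    )
    return geom, flat_panel_policy(ctr_ps=cfg.ctr_ps, level=cfg.readout)
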