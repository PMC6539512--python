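"""Ballesteros–Weinstein (BW) residue numbering for GPCR transmembrane helices.

Each helix H carries a single anchor: the most conserved residue of that helix
is labeled H.50, the residue before it H.49, the one after H.51, and so on —
the label index runs contiguously with the absolute sequence position inside
the helix span.  Residues in loops and termini have no BW label and are
referred to by their absolute sequence number only.

A packaged reference map for human GPR18 is provided.  Its TMH3 anchoring is
fixed by the documented A3.39 = Ala(108) equivalence; the remaining spans are
the complements of the documented loop spans and are marked approximate in
the map's provenance notes (the receptor's helix net is the only public
source for them).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["BWLabel", "LabelMap", "build_label_map", "gpr18_reference_map"]


class ConfigError(ValueError):
    """Inconsistent anchor/span configuration."""


_BW_RE = re.compile(r"^([1-8])\.(\d{1,2})$")


@dataclass(frozen=True, order=True)
class BWLabel:
    """A helix.position label, e.g. 3.50."""

    helix: int
    position: int

    def __post_init__(self) -> None:
        if not 1 <= self.helix <= 8:
            raise ValueError(f"helix must be 1–8, got {self.helix}")
        if not 1 <= self.position <= 99:
            raise ValueError(f"position must be 1–99, got {self.position}")

    def __str__(self) -> str:
        return f"{self.helix}.{self.position:02d}"

    @classmethod
    def parse(cls, text: str | "BWLabel") -> "BWLabel":
        if isinstance(text, BWLabel):
            return text
        m = _BW_RE.match(str(text).strip())
        if not m:
            raise ValueError(f"not a BW label: {text!r}")
        return cls(int(m.group(1)), int(m.group(2)))


@dataclass
class LabelMap:
    """Bidirectional absolute ↔ BW map built from per-helix anchors and spans."""

    anchors: dict[int, int]           # helix -> absolute index of the x.50 residue
    spans: dict[int, tuple[int, int]]  # helix -> (first, last) absolute index
    known_residues: dict[int, str] = field(default_factory=dict)  # abs -> 3-letter code
    notes: str = ""

    _abs_to_bw: dict[int, BWLabel] = field(default=None, repr=False)  # type: ignore[assignment]
    _bw_to_abs: dict[BWLabel, int] = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        prev_last = None
        for h in sorted(self.spans):
            first, last = self.spans[h]
            if first > last:
                raise ConfigError(f"helix {h}: span ({first},{last}) reversed")
            if h not in self.anchors:
                raise ConfigError(f"helix {h}: span given without anchor")
            if not first <= self.anchors[h] <= last:
                raise ConfigError(
                    f"helix {h}: anchor {self.anchors[h]} outside span ({first},{last})"
                )
            if prev_last is not None and first <= prev_last:
                raise ConfigError(f"helix {h}: span overlaps or is out of order")
            prev_last = last
        for h in self.anchors:
            if h not in self.spans:
                raise ConfigError(f"helix {h}: anchor given without span")
        self._abs_to_bw = {}
        self._bw_to_abs = {}
        for h, (first, last) in self.spans.items():
            anchor = self.anchors[h]
            for i in range(first, last + 1):
                pos = 50 + (i - anchor)
                if not 1 <= pos <= 99:
                    raise ConfigError(f"helix {h}: residue {i} maps outside 1–99")
                lbl = BWLabel(h, pos)
                self._abs_to_bw[i] = lbl
                self._bw_to_abs[lbl] = i

    def abs_to_bw(self, abs_index: int) -> BWLabel | None:
        """BW label for a helix residue; None for loop/terminal residues."""
        return self._abs_to_bw.get(abs_index)

    def bw_to_abs(self, label: str | BWLabel) -> int:
        lbl = BWLabel.parse(label)
        try:
            return self._bw_to_abs[lbl]
        except KeyError:
            raise KeyError(f"BW label {lbl} not covered by this map") from None

    def helix_residues(self, helix: int) -> list[int]:
        first, last = self.spans[helix]
        return list(range(first, last + 1))

    # --- YAML (de)serialization; the CLI's --labels flag reads this format ---

    def to_yaml(self, path: str | Path | None = None) -> str:
        doc = {
            "helices": {
                int(h): {"span": [int(a), int(b)], "anchor": int(self.anchors[h])}
                for h, (a, b) in sorted(self.spans.items())
            },
            "known_residues": {int(k): v for k, v in sorted(self.known_residues.items())},
            "notes": self.notes,
        }
        text = yaml.safe_dump(doc, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "LabelMap":
        text = Path(source).read_text() if isinstance(source, Path) or "\n" not in str(source) else str(source)
        doc = yaml.safe_load(text)
        helices = doc.get("helices", {})
        anchors = {int(h): int(v["anchor"]) for h, v in helices.items()}
        spans = {int(h): (int(v["span"][0]), int(v["span"][1])) for h, v in helices.items()}
        return cls(
            anchors=anchors,
            spans=spans,
            known_residues={int(k): v for k, v in doc.get("known_residues", {}).items()},
            notes=doc.get("notes", ""),
        )


def build_label_map(
    sequence: str | None,
    anchors: dict[int, int],
    spans: dict[int, tuple[int, int]],
    **kwargs,
) -> LabelMap:
    """Build a LabelMap, optionally recording residue identities from a sequence.

    ``sequence`` is a 1-letter amino-acid string indexed from 1; when given,
    every helix residue's 3-letter code is recorded in ``known_residues``.
    """
    known: dict[int, str] = dict(kwargs.pop("known_residues", {}))
    if sequence is not None:
        from .helix_geometry import ONE_TO_THREE

        for h, (first, last) in spans.items():
            if last > len(sequence):
                raise ConfigError(f"helix {h}: span end {last} beyond sequence length")
            for i in range(first, last + 1):
                aa = sequence[i - 1].upper()
                if aa not in ONE_TO_THREE:
                    raise ConfigError(f"unknown residue letter {aa!r} at position {i}")
                known[i] = ONE_TO_THREE[aa]
    return LabelMap(anchors=anchors, spans=spans, known_residues=known, **kwargs)


#: Loop spans documented for human GPR18 (absolute residue numbers).
GPR18_LOOPS = {
    "N-term": (1, 18),
    "IC-1": (51, 55),
    "EC-1": (86, 90),
    "IC-2": (126, 133),
    "EC-2": (159, 184),
    "IC-3": (216, 226),
    "EC-3": (259, 264),
}

# Residue identities documented for GPR18 at specific positions.
_GPR18_KNOWN = {
    94: "CYS",    # C3.25, disulfide partner of C(172)
    101: "THR",   # T3.32
    105: "PRO",   # P3.36 — the TMH3 hinge unique to GPR18
    108: "ALA",   # A3.39 (the constitutive-activity mutation site)
    118: "ASP",   # D3.49
    119: "ARG",   # R3.50
    120: "TYR",   # Y3.51
    125: "GLN",   # Q3.56
    172: "CYS",   # EC-2 cysteine
    227: "LYS",   # K6.30
    230: "SER",   # S6.33 — the GPR18 "ionic lock" partner of R3.50
    231: "ILE",   # I6.34
    234: "ILE",   # I6.37
    240: "GLN",   # Q6.43
    244: "CYS",   # C6.47
    245: "PHE",   # F6.48 — toggle switch
    247: "PRO",   # P6.50
    249: "HIS",   # H6.52
}


def gpr18_reference_map() -> LabelMap:
    """Packaged BW map for human GPR18.

    TMH3 is anchored by A3.39 = Ala(108) (hence R3.50 = 119); TMH6 by the
    documented cytoplasmic start K6.30 = Lys(227).  Helix spans are the
    complements of the documented loop spans; anchors for helices 1, 2, 4, 5,
    7 and 8 are placed consistently with typical class A geometry and are
    approximate (see ``notes``).  Loop residues resolve to absolute numbers
    only.
    """
    anchors = {
        1: 43,    # N1.50 (approximate within TMH1 span)
        2: 70,    # D2.50 (approximate)
        3: 119,   # R3.50, fixed by A3.39 = 108
        4: 147,   # W4.50 (approximate)
        5: 201,   # P5.50 (approximate)
        6: 247,   # P6.50, fixed by K6.30 = 227
        7: 282,   # V7.50 (approximate; GPR18 has DVXXY, not NPXXY)
        8: 295,   # helix 8 (approximate)
    }
    spans = {
        1: (19, 50),
        2: (56, 85),
        3: (91, 125),
        4: (134, 158),
        5: (185, 215),
        6: (227, 258),
        7: (265, 289),
        8: (291, 299),
    }
    notes = (
        "TMH spans are figure-derived, approximate: they are the complements of "
        "the documented loop spans (N-term 1-18, IC-1 51-55, EC-1 86-90, IC-2 "
        "126-133, EC-2 159-184, IC-3 216-226, EC-3 259-264). TMH3 anchoring is "
        "fixed by A3.39=Ala(108); TMH6 by K6.30=Lys(227). Anchors for helices "
        "1,2,4,5,7,8 are approximate. Source discrepancy: the mutation site is "
        "printed both as A3.39(108)N and A3.93(102)N; this map adopts 3.39=108, "
        "the reading with a well-formed BW label."
    )
    return LabelMap(anchors=anchors, spans=spans, known_residues=dict(_GPR18_KNOWN), notes=notes)
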