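"""Honey classes, marker registry, and assay constants.

Honey type is a six-level factor: monofloral manuka (M), multifloral manuka
(MB), kanuka (K), non-manuka (NM), Australian (AU) and non-NZ/Aus (NN).
Sensitivity analyses also use a four-level collapse in which kanuka joins
non-manuka and the two overseas classes merge.

Markers are of two kinds: chemical markers measured as concentrations
(mg/kg in honey, mg/L in nectar; left-censored at the limit of reporting)
and qPCR DNA markers measured as a quantification cycle (Cq), where a lower
Cq means more target DNA. Cq 36 is the detection LOR and 40 the assay
maximum.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass


class HoneyType(str, enum.Enum):
    """Six-level honey type factor used as the classification response."""

    M = "M"    # monofloral manuka
    MB = "MB"  # multifloral manuka
    K = "K"    # kanuka
    NM = "NM"  # non-manuka (e.g. clover)
    AU = "AU"  # Australian
    NN = "NN"  # non-NZ/Aus

    @property
    def description(self) -> str:
        return _DESCRIPTIONS[self]


_DESCRIPTIONS = {
    HoneyType.M: "monofloral manuka",
    HoneyType.MB: "multifloral manuka",
    HoneyType.K: "kanuka",
    HoneyType.NM: "non-manuka",
    HoneyType.AU: "Australian",
    HoneyType.NN: "non-NZ/Aus",
}

#: Four-level collapse used by the class-coarsening sensitivity scenario:
#: kanuka merges into non-manuka and both overseas classes merge into a
#: single non-New-Zealand class (labelled by its AU/NN union as "NN").
FOUR_CLASS_COLLAPSE: dict[str, str] = {
    "M": "M",
    "MB": "MB",
    "K": "NM",
    "NM": "NM",
    "AU": "NN",
    "NN": "NN",
}


def collapse_to_four(label: str | HoneyType) -> str:
    """Map a six-level honey type label to the four-level coarsening."""
    key = label.value if isinstance(label, HoneyType) else str(label)
    try:
        return FOUR_CLASS_COLLAPSE[key]
    except KeyError:
        raise ValueError(f"unknown honey type label: {label!r}") from None


class MarkerKind(str, enum.Enum):
    CHEMICAL = "chemical"
    DNA = "dna"


@dataclass(frozen=True)
class Marker:
    """A named marker with its measurement kind.

    Chemical markers carry mg/kg (honey) or mg/L (nectar) units; DNA markers
    carry Cq units.
    """

    name: str
    kind: MarkerKind

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


CHEMICAL_MARKERS: tuple[str, ...] = (
    "2'-MAP",        # 2'-methoxyacetophenone
    "2-MBA",         # 2-methoxybenzoic acid
    "3-PA",          # 3-phenyllactic acid
    "4-HPA",         # 4-hydroxyphenyllactic acid
    "MS",            # methyl syringate
    "leptosperin",
    "DHA",           # dihydroxyacetone
    "MG",            # methylglyoxal
    "kojic_acid",
    "4-MPA",         # 4-methoxyphenyllactic acid
    "lumichrome",
)

DNA_MARKERS: tuple[str, ...] = ("manuka_dna", "kanuka_dna")

ALL_MARKERS: tuple[str, ...] = CHEMICAL_MARKERS + DNA_MARKERS

MARKER_REGISTRY: dict[str, Marker] = {
    **{m: Marker(m, MarkerKind.CHEMICAL) for m in CHEMICAL_MARKERS},
    **{m: Marker(m, MarkerKind.DNA) for m in DNA_MARKERS},
}


def marker_kind(name: str) -> MarkerKind:
    try:
        return MARKER_REGISTRY[name].kind
    except KeyError:
        raise ValueError(f"unknown marker: {name!r}") from None


# Assay constants -----------------------------------------------------------

#: Limit of reporting for chemical markers in honey (mg/kg).
HONEY_LOR = 1.0
#: Limit of reporting for chemical markers in nectar (mg/L).
NECTAR_LOR = 0.01
#: Cq detection limit of reporting for the qPCR DNA assays.
CQ_LOR = 36.0
#: Maximum assay Cq value.
CQ_MAX = 40.0

#: The five nectar-collection habitat types.
HABITATS: tuple[str, ...] = (
    "calcareous soil",
    "coastal sand/headland",
    "dry ridge",
    "low-altitude bog",
    "montane",
)

#: The three production-year levels: two honey production years plus archive.
YEARS: tuple[str, ...] = ("2014/15", "2015/16", "archive")

#: Twelve-level regional classification for New Zealand samples, with island.
NZ_REGIONS: dict[str, str] = {
    "Northland": "North",
    "Auckland": "North",
    "Waikato": "North",
    "Bay of Plenty": "North",
    "Gisborne": "North",
    "Hawke's Bay": "North",
    "Taranaki": "North",
    "Manawatu-Wanganui": "North",
    "Tasman": "South",
    "West Coast": "South",
    "Canterbury": "South",
    "Otago": "South",
}
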