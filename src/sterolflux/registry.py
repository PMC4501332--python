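"""Sterol registry: identities, fragment-ion compositions, pathway roles.

The assay detects each sterol as its dehydrated protonated ion
([M+H-H2O]+), so fragment formulas carry no oxygen: a sterol C(c)H(h)O
yields a fragment C(c)H(h-1)+ at nominal m/z 12*c + (h-1). Carbon counts are
what drive the natural-abundance model; nominal m/z values identify the
acquisition channel.

Masking rules follow the assay's isobaric-interference constraints:
cholesterol saturates the detector at m/z 369, removing lathosterol and
zymostenol entirely, and its own isotopomer envelope bleeds into m/z 367
above M+1, so the m/z-367 sterols (desmosterol, 7-dehydrocholesterol,
zymosterol) are quantified from their M+0 and M+1 peaks only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import ConfigurationError
from .isotopes import FragmentFormula

__all__ = ["SterolDefinition", "SterolRegistry", "default_registry",
           "BLOCH_ORDER", "KR_ORDER"]

#: Pathway order of the measurable Bloch intermediates (upstream -> terminal).
BLOCH_ORDER = [
    "lanosterol", "ff-MAS", "t-MAS", "zymosterol",
    "dehydrolathosterol", "dehydrodesmosterol", "desmosterol",
]

#: Pathway order of the (modified) Kandutsch-Russell branch.
KR_ORDER = [
    "dihydrolanosterol", "dihydro-ff-MAS", "dihydro-t-MAS",
    "zymostenol", "lathosterol", "7-dehydrocholesterol",
]


@dataclass(frozen=True)
class SterolDefinition:
    """One sterol as seen by the assay."""

    name: str
    carbons: int
    hydrogens: int
    oxygens: int
    nominal_mz: int
    pathway: str                      # {bloch, kr, shared, off-pathway, standard}
    measurable: bool = True
    #: isotopomer shifts that survive isobaric masking; None = full window
    measurable_shifts: tuple[int, ...] | None = None
    masking_note: str = ""

    @property
    def formula(self) -> FragmentFormula:
        return FragmentFormula(self.carbons, self.hydrogens, self.oxygens)


def _mk(name, c, h, mz, pathway, measurable=True, shifts=None, note=""):
    return SterolDefinition(name, c, h, 0, mz, pathway, measurable, shifts, note)


_DEFAULT_STEROLS = [
    # Bloch branch (side chain stays unsaturated until desmosterol)
    _mk("lanosterol", 30, 49, 409, "bloch"),
    _mk("ff-MAS", 29, 45, 393, "bloch"),
    _mk("t-MAS", 29, 47, 395, "bloch"),
    _mk("zymosterol", 27, 43, 367, "bloch", shifts=(0, 1),
        note="cholesterol envelope saturates >M+1 at m/z 367"),
    _mk("dehydrolathosterol", 27, 43, 367, "bloch", measurable=False,
        note="concentration below detection limit in all tissues"),
    _mk("dehydrodesmosterol", 27, 41, 365, "bloch"),
    _mk("desmosterol", 27, 43, 367, "bloch", shifts=(0, 1),
        note="cholesterol envelope saturates >M+1 at m/z 367"),
    # K-R / MK-R branch (saturated side chain)
    _mk("dihydrolanosterol", 30, 51, 411, "kr"),
    _mk("dihydro-ff-MAS", 29, 47, 395, "kr"),
    _mk("dihydro-t-MAS", 29, 49, 397, "kr"),
    _mk("zymostenol", 27, 45, 369, "kr", measurable=False,
        note="isobaric with cholesterol; signal saturated"),
    _mk("lathosterol", 27, 45, 369, "kr", measurable=False,
        note="isobaric with cholesterol; signal saturated"),
    _mk("7-dehydrocholesterol", 27, 43, 367, "kr", shifts=(0, 1),
        note="cholesterol envelope saturates >M+1 at m/z 367"),
    # Product and standards
    _mk("cholesterol", 27, 45, 369, "shared", measurable=False,
        note="saturates the detector"),
    _mk("d6-sitosterol", 29, 49, 404, "standard",
        note="internal standard, 20 ng spike"),
]


@dataclass
class SterolRegistry:
    """Lookup table of :class:`SterolDefinition` by name."""

    sterols: dict[str, SterolDefinition] = field(default_factory=dict)

    def __contains__(self, name: str) -> bool:
        return name in self.sterols

    def __getitem__(self, name: str) -> SterolDefinition:
        try:
            return self.sterols[name]
        except KeyError:
            raise ConfigurationError(f"sterol {name!r} not in registry") from None

    def names(self) -> list[str]:
        return list(self.sterols)

    def measurable(self) -> list[SterolDefinition]:
        return [s for s in self.sterols.values()
                if s.measurable and s.pathway != "standard"]

    def shifts_for(self, name: str, window: int) -> tuple[int, ...]:
        """Measurable isotopomer shifts for a sterol within a window."""
        s = self[name]
        if s.measurable_shifts is not None:
            return tuple(i for i in s.measurable_shifts if i <= window)
        return tuple(range(window + 1))

    def add(self, sterol: SterolDefinition) -> None:
        self.sterols[sterol.name] = sterol

    # -- delimited-text round trip ------------------------------------------

    _COLUMNS = ["name", "carbons", "hydrogens", "oxygens", "nominal_mz",
                "pathway", "measurable", "measurable_shifts", "masking_note"]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.sterols.values():
            shifts = "" if s.measurable_shifts is None else \
                ";".join(str(i) for i in s.measurable_shifts)
            rows.append([s.name, s.carbons, s.hydrogens, s.oxygens, s.nominal_mz,
                         s.pathway, s.measurable, shifts, s.masking_note])
        return pd.DataFrame(rows, columns=self._COLUMNS)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SterolRegistry":
        df = pd.read_csv(path, dtype={"masking_note": str}, keep_default_na=False)
        missing = set(cls._COLUMNS) - set(df.columns)
        if missing:
            raise ConfigurationError(f"registry file missing columns: {sorted(missing)}")
        reg = cls()
        for _, r in df.iterrows():
            shifts = None
            if str(r["measurable_shifts"]).strip():
                shifts = tuple(int(x) for x in str(r["measurable_shifts"]).split(";"))
            measurable = str(r["measurable"]).strip().lower() in ("true", "1")
            reg.add(SterolDefinition(
                str(r["name"]), int(r["carbons"]), int(r["hydrogens"]),
                int(r["oxygens"]), int(r["nominal_mz"]), str(r["pathway"]),
                measurable, shifts, str(r["masking_note"])))
        return reg


def default_registry() -> SterolRegistry:
    """Registry covering the post-squalene pathway as the assay sees it."""
    reg = SterolRegistry()
    for s in _DEFAULT_STEROLS:
        reg.add(s)
    return reg
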