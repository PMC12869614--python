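"""Registry of per-species / per-agent / per-tissue relaxometry constants.

Pre-contrast T1 is fixed per tissue (no per-subject T1 mapping): 581 ms for
liver, 1172 ms for spleen and 1480 ms for blood.  In-situ relaxivities are
agent- and tissue-specific; EES volume fractions are 0.23 (liver) and 0.43
(spleen).  The packaged table can be overridden or extended with a user CSV
of the same schema (``species,agent,tissue,t1_0_ms,r1,ve``).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

SPECIES = ("dog", "pig")
AGENTS = ("Gd-EOB-DTPA", "Gd-BOPTA", "Gd-BT-DO3A", "Gd-DTPA")
TISSUES = ("liver", "spleen", "blood")

#: agents actively taken up by hepatocytes (OATP substrates)
HEPATOSPECIFIC_AGENTS = frozenset({"Gd-EOB-DTPA", "Gd-BOPTA"})


def is_hepatospecific(agent: str) -> bool:
    return agent in HEPATOSPECIFIC_AGENTS


@dataclass(frozen=True)
class TissueConstants:
    """Relaxometry constants for one (species, agent, tissue) combination.

    t1_0 is the pre-contrast T1 in ms, r1 the in-situ relaxivity in
    s^-1 mM^-1, ve the EES volume fraction (liver/spleen only, else None).
    """

    species: str
    agent: str
    tissue: str
    t1_0: float
    r1: float
    ve: float | None = None

    def __post_init__(self):
        if self.t1_0 <= 0:
            raise ValueError("t1_0 must be > 0")
        if self.r1 <= 0:
            raise ValueError("r1 must be > 0")
        if self.ve is not None and not 0 < self.ve < 1:
            raise ValueError("ve must be in (0, 1)")

    @property
    def r1_0(self) -> float:
        """Pre-contrast longitudinal relaxation rate R1(0) in s^-1."""
        return 1000.0 / self.t1_0


class ConstantsRegistry:
    """Lookup table of :class:`TissueConstants`, loadable from CSV."""

    def __init__(self, table: pd.DataFrame):
        self._entries: dict[tuple[str, str, str], TissueConstants] = {}
        for row in table.itertuples(index=False):
            ve = None if pd.isna(row.ve) else float(row.ve)
            tc = TissueConstants(
                species=str(row.species),
                agent=str(row.agent),
                tissue=str(row.tissue),
                t1_0=float(row.t1_0_ms),
                r1=float(row.r1),
                ve=ve,
            )
            self._entries[(tc.species, tc.agent, tc.tissue)] = tc

    @classmethod
    def default(cls) -> "ConstantsRegistry":
        with resources.files("liverdce.data").joinpath("constants.csv").open() as fh:
            return cls(pd.read_csv(fh))

    @classmethod
    def from_csv(cls, path) -> "ConstantsRegistry":
        return cls(pd.read_csv(path))

    def override(self, path) -> "ConstantsRegistry":
        """New registry with rows from *path* replacing/extending this one."""
        merged = ConstantsRegistry(pd.DataFrame(columns=["species", "agent", "tissue", "t1_0_ms", "r1", "ve"]))
        merged._entries = dict(self._entries)
        merged._entries.update(ConstantsRegistry.from_csv(path)._entries)
        return merged

    def lookup(self, species: str, agent: str, tissue: str) -> TissueConstants:
        try:
            return self._entries[(species, agent, tissue)]
        except KeyError:
            known = sorted({a for (_, a, _) in self._entries})
            raise KeyError(
                f"no constants for species={species!r}, agent={agent!r}, tissue={tissue!r}; "
                f"known agents: {known}"
            ) from None

    def __iter__(self):
        return iter(self._entries.values())

    def __len__(self) -> int:
        return len(self._entries)


_DEFAULT: ConstantsRegistry | None = None


def default_registry() -> ConstantsRegistry:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = ConstantsRegistry.default()
    return _DEFAULT
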