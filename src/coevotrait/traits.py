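"""Binary trait observations (gene present/absent/uncertain) per species."""

from __future__ import annotations

from collections.abc import Mapping
from pathlib import Path
from typing import Iterator

import pandas as pd

__all__ = ["TraitStates", "UNCERTAIN"]

UNCERTAIN = "?"
_VALID = {"0", "1", UNCERTAIN}


class TraitStates(Mapping):
    """Mapping species -> state in {0 (absent/incomplete), 1 (present), '?'}.

    States may be given as ints or strings; they are normalized to the
    three-symbol string alphabet {'0', '1', '?'}.
    """

    def __init__(self, states: Mapping[str, object]):
        norm: dict[str, str] = {}
        for sp, st in states.items():
            s = str(st).strip()
            if s not in _VALID:
                raise ValueError(
                    f"invalid state {st!r} for species {sp!r}; expected 0, 1 or '?'"
                )
            norm[str(sp)] = s
        self._states = norm

    def __getitem__(self, species: str) -> str:
        return self._states[species]

    def __iter__(self) -> Iterator[str]:
        return iter(self._states)

    def __len__(self) -> int:
        return len(self._states)

    @property
    def species(self) -> list[str]:
        return list(self._states)

    def n_uncertain(self) -> int:
        return sum(1 for v in self._states.values() if v == UNCERTAIN)

    def is_variable(self) -> bool:
        """True iff both certain states are observed at least once... no:
        a gene enters the screen iff its certain calls are not all identical."""
        seen = {v for v in self._states.values() if v != UNCERTAIN}
        return len(seen) > 1

    def restrict(self, species: set[str]) -> "TraitStates":
        return TraitStates({s: v for s, v in self._states.items() if s in species})

    # -- I/O --------------------------------------------------------------

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TraitStates":
        """Read a two-column headerless TSV: species<TAB>state."""
        df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
        if df.shape[1] < 2:
            raise ValueError(f"{path}: expected two tab-separated columns")
        return cls(dict(zip(df.iloc[:, 0], df.iloc[:, 1])))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for sp, st in self._states.items():
                fh.write(f"{sp}\t{st}\n")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<TraitStates for {len(self)} species>"
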