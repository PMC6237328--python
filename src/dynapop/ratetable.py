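"""Age- and sex-indexed rate tables.

Every epidemiological input to the simulation — risk-factor state
prevalence, disease prevalence, incidence, attributable (excess)
mortality, acute fatality, cured fractions, relative risks — is a
quantity defined for each sex and each integer year of age.  A
:class:`RateTable` stores one such quantity on the grid
``(sex in {male, female}) x (age in 0..a_max)``, with rates understood
as per person-year and probabilities/fractions as dimensionless numbers
in [0, 1].  Rates are piecewise-constant on the half-open year
intervals ``[a, a+1)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

#: Canonical sex labels, in storage order.
SEXES: tuple[str, str] = ("male", "female")

_SEX_INDEX = {s: i for i, s in enumerate(SEXES)}


def sex_index(sex: str) -> int:
    """Map a sex label to its row index in a rate table."""
    try:
        return _SEX_INDEX[sex]
    except KeyError:
        raise ValueError(f"unknown sex {sex!r}; expected one of {SEXES}") from None


@dataclass(frozen=True)
class RateTable:
    """One quantity indexed by sex and integer age.

    Parameters
    ----------
    name:
        Name of the quantity (e.g. ``"incidence:lung_cancer"``).
    values:
        Array of shape ``(2, a_max + 1)``; row 0 is male, row 1 female.
    """

    name: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != 2 or v.shape[1] < 2:
            raise ValueError(
                f"{self.name}: values must have shape (2, a_max+1) with a_max >= 1, "
                f"got {v.shape}"
            )
        object.__setattr__(self, "values", v)

    # -- construction -------------------------------------------------
    @classmethod
    def constant(cls, name: str, value: float, a_max: int) -> "RateTable":
        """A table with the same value at every (sex, age)."""
        return cls(name, np.full((2, a_max + 1), float(value)))

    @classmethod
    def from_function(
        cls, name: str, fn: Callable[[str, np.ndarray], np.ndarray], a_max: int
    ) -> "RateTable":
        """Build from ``fn(sex, ages) -> values`` evaluated per sex."""
        ages = np.arange(a_max + 1)
        rows = [np.broadcast_to(np.asarray(fn(s, ages), dtype=float), ages.shape) for s in SEXES]
        return cls(name, np.vstack(rows))

    # -- access -------------------------------------------------------
    @property
    def a_max(self) -> int:
        return self.values.shape[1] - 1

    def value(self, sex: str, age: int) -> float:
        return float(self.values[sex_index(sex), age])

    def sex_values(self, sex: str) -> np.ndarray:
        """The full age profile for one sex (read-only view)."""
        return self.values[sex_index(sex)]

    # -- transforms ---------------------------------------------------
    def capped(self, cap: int) -> "RateTable":
        """Hold the value constant above age ``cap`` (see scenario.cap_rates_above_age)."""
        if cap > self.a_max:
            raise ValueError(
                f"{self.name}: cap beyond table range (cap={cap}, a_max={self.a_max})"
            )
        v = self.values.copy()
        v[:, cap + 1 :] = v[:, [cap]]
        return RateTable(self.name, v)

    def scaled(self, factor: float) -> "RateTable":
        return RateTable(self.name, self.values * float(factor))

    # -- I/O ------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Long format with columns ``sex, age, value``."""
        ages = np.arange(self.a_max + 1)
        return pd.DataFrame(
            {
                "sex": np.repeat(SEXES, len(ages)),
                "age": np.tile(ages, 2),
                "value": self.values.ravel(),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, name: str, frame: pd.DataFrame) -> "RateTable":
        required = {"sex", "age", "value"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"{name}: rate CSV missing columns {sorted(missing)}")
        ages = np.sort(frame["age"].unique())
        a_max = int(ages.max())
        expected = np.arange(a_max + 1)
        values = np.full((2, a_max + 1), np.nan)
        for s in SEXES:
            sub = frame[frame["sex"] == s].sort_values("age")
            if not np.array_equal(sub["age"].to_numpy(), expected):
                raise ValueError(
                    f"{name}: ages for sex {s!r} must be exactly 0..{a_max} "
                    f"with no gaps or duplicates"
                )
            values[sex_index(s)] = sub["value"].to_numpy(dtype=float)
        return cls(name, values)

    @classmethod
    def read_csv(cls, path, name: str | None = None) -> "RateTable":
        # round_trip parser: bit-exact reload of %.17g-formatted values
        frame = pd.read_csv(path, float_precision="round_trip")
        return cls.from_frame(name or str(path), frame)

    # -- equality (exact, for round-trip tests) -----------------------
    def allclose(self, other: "RateTable", atol: float = 0.0) -> bool:
        return self.values.shape == other.values.shape and np.allclose(
            self.values, other.values, rtol=0.0, atol=atol
        )
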