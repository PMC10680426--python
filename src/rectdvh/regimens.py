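"""The three fractionation regimens under comparison."""

from __future__ import annotations

import enum

from .errors import ConfigError

__all__ = ["Arm"]


class Arm(enum.Enum):
    """Radiotherapy regimen: prescription dose / number of fractions."""

    FR37 = ("74Gy/37Fr", 74.0, 37)
    FR20 = ("60Gy/20Fr", 60.0, 20)
    FR19 = ("57Gy/19Fr", 57.0, 19)

    def __init__(self, label: str, prescription_gy: float, n_fractions: int) -> None:
        self.label = label
        self.prescription_gy = prescription_gy
        self.n_fractions = n_fractions

    @property
    def dose_per_fraction_gy(self) -> float:
        return self.prescription_gy / self.n_fractions

    @classmethod
    def parse(cls, text: "str | Arm") -> "Arm":
        """Accepts an Arm, its label, its name, or shorthands like '37Fr'."""
        if isinstance(text, Arm):
            return text
        key = str(text).strip().lower().replace(" ", "")
        for arm in cls:
            if key in {
                arm.label.lower(),
                arm.name.lower(),
                f"{arm.n_fractions}fr",
                f"{arm.prescription_gy:g}gy",
            }:
                return arm
        raise ConfigError(f"unknown arm {text!r}; expected one of {[a.label for a in cls]}")
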