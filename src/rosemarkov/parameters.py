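"""Annual transition probabilities of the four-state illness-death chain.

States are numbered 1 = healthy, 2 = mentally ill, 3 = death from causes
other than suicide, 4 = death by suicide.  ``p_ij`` is the probability that
an individual in state *j* at the start of a year is in state *i* at the
end of it, so the six free parameters are the off-diagonal flows out of the
two living states::

    p21  healthy -> mentally ill   (incidence of diagnosed mental illness)
    p12  mentally ill -> healthy   (recovery)
    p31  healthy -> other death
    p32  mentally ill -> other death
    p41  healthy -> suicide
    p42  mentally ill -> suicide

Each probability lies in [0, 1] and the exits from each living state must
not exceed 1 (the remainder is the stay probability).
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping
from dataclasses import dataclass

PARAM_NAMES: tuple[str, ...] = ("p21", "p12", "p31", "p32", "p41", "p42")


class ParameterError(ValueError):
    """A transition probability is out of range or a row sum exceeds 1."""


@dataclass(frozen=True)
class TransitionParameters:
    """The six annual transition probabilities of the chain.

    Instances are immutable; use :meth:`replace` to derive perturbed
    parameter sets (for sensitivity scans) with re-validation.
    """

    p21: float
    p12: float
    p31: float
    p32: float
    p41: float
    p42: float

    @property
    def healthy_exit(self) -> float:
        """Total annual exit probability from the healthy state."""
        return self.p21 + self.p31 + self.p41

    @property
    def ill_exit(self) -> float:
        """Total annual exit probability from the mentally ill state
        (often written S = p12 + p32 + p42)."""
        return self.p12 + self.p32 + self.p42

    def validate(self) -> "TransitionParameters":
        """Return ``self`` if all invariants hold, else raise ParameterError."""
        for name in PARAM_NAMES:
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ParameterError(
                    f"invalid probability: {name}={value!r} is outside [0, 1]"
                )
        if self.healthy_exit > 1.0:
            raise ParameterError(
                "row overflow: healthy-state exits p21 + p31 + p41 = "
                f"{self.healthy_exit:.6g} exceed 1"
            )
        if self.ill_exit > 1.0:
            raise ParameterError(
                "row overflow: ill-state exits p12 + p32 + p42 = "
                f"{self.ill_exit:.6g} exceed 1"
            )
        return self

    def replace(self, **changes: float) -> "TransitionParameters":
        """A copy with the given probabilities substituted and validated."""
        unknown = set(changes) - set(PARAM_NAMES)
        if unknown:
            raise ParameterError(f"unknown parameter(s): {sorted(unknown)}")
        return dataclasses.replace(self, **changes).validate()

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PARAM_NAMES}

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float]) -> "TransitionParameters":
        """Build from any mapping holding the six ``p_ij`` keys."""
        missing = [name for name in PARAM_NAMES if name not in mapping]
        if missing:
            raise ParameterError(f"missing parameter(s): {missing}")
        return cls(**{name: float(mapping[name]) for name in PARAM_NAMES}).validate()


def validate_parameters(params: TransitionParameters) -> TransitionParameters:
    """Functional alias for :meth:`TransitionParameters.validate`."""
    return params.validate()


#: Hong Kong 2012 annual transition probabilities (public psychiatric-service
#: morbidity and Coroner court estimates), the package's default scenario.
HONG_KONG_2012 = TransitionParameters(
    p21=0.00286,   # incidence of diagnosed mental illness
    p12=0.0667,    # recovery
    p31=0.006,     # other-cause death, healthy
    p32=0.012,     # other-cause death, mentally ill
    p41=0.0000834, # suicide, healthy (8.34 per 100,000)
    p42=0.0025,    # suicide, mentally ill (250 per 100,000)
).validate()

#: Hong Kong total population used with the default scenario.
HONG_KONG_Q0 = 7_000_000

#: Prevalent psychiatric-service users used as the default initial ill stock.
HONG_KONG_INITIAL_ILL = 150_000
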