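"""Model parameters for the indirect-response VA drug-disease model.

The disease state is best-corrected visual acuity (VA, ETDRS letters).
Untreated, VA relaxes toward a steady state ``g_ss`` with rate ``k_out``:

    dg/dt = k_in - k_out * g,      k_in = g_ss * k_out

Intravitreal ranibizumab stimulates the production rate ``k_in`` through a
Hill term in the vitreous drug concentration C(t), scaled by a maximum
effect Emax that is larger at baseline (loading phase) and decays toward an
age-dependent steady state:

    dg/dt = k_in * (1 + Emax(t) * C/(EC50 + C)) - k_out * g
    Emax(t) = Emax_ss(age) + alpha * dEmax0 * exp(-k_emax * t)
    log Emax_ss(age) = log emax0_ss + beta * log(age / 77)

``alpha`` scales the transient loading effect by pre-treatment status
(treatment-naive patients get the full effect).

Units note: the vitreous volume is not modelled, so concentration is carried
in dose units (mg of ranibizumab remaining in the eye) and ``ec50`` absorbs
the volume scale.  Only the ratio C/EC50 is ever used.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace

__all__ = ["ModelParameters", "DEFAULT_PARAMETERS", "RANIBIZUMAB_HALF_LIFE_DAYS"]

#: Vitreous elimination half-life used for the fixed PK constant (days).
RANIBIZUMAB_HALF_LIFE_DAYS = 9.0


@dataclass(frozen=True)
class ModelParameters:
    """All rate and effect constants of the VA model.

    Parameters
    ----------
    g_ss : float
        Steady-state VA without treatment (ETDRS letters), in (0, 100].
    k_out : float
        VA deterioration rate (1/day), > 0.  ``k_in`` is always derived as
        ``g_ss * k_out`` and never stored.
    ec50 : float
        Half-effect concentration in dose-normalized units (mg), > 0.
    emax0_ss : float
        Population steady-state Emax at the reference age of 77 years.
    d_emax0 : float
        Baseline increment of Emax (loading-phase bonus before decay).
    k_emax : float
        Decay rate of the baseline Emax increment (1/day), >= 0.  The decay
        clock starts at study baseline (diagnosis), not at first injection,
        which is the mechanism by which treatment delay destroys benefit.
    beta : float
        Age exponent on log-Emax (negative: older patients respond less).
    alpha_naive, alpha_pretreated, alpha_possibly : float
        Pre-treatment scaling of the transient effect.  ``alpha_naive`` is
        fixed at 1 by convention; ``alpha_possibly`` defaults to the
        pretreated value when ``None``.
    k_drug : float
        First-order vitreous elimination rate (1/day), fixed, not estimated.
    """

    g_ss: float = 35.0
    k_out: float = 0.0025
    ec50: float = 0.04
    emax0_ss: float = 1.5
    d_emax0: float = 1.5
    k_emax: float = 0.01
    beta: float = -2.0
    alpha_naive: float = 1.0
    alpha_pretreated: float = 0.3
    alpha_possibly: float | None = None
    k_drug: float = field(default=math.log(2.0) / RANIBIZUMAB_HALF_LIFE_DAYS)

    def __post_init__(self) -> None:
        self.validate()

    # -- derived quantities -------------------------------------------------
    @property
    def k_in(self) -> float:
        """Production rate (letters/day), derived: k_in = g_ss * k_out."""
        return self.g_ss * self.k_out

    def alpha_for(self, pretreatment: str) -> float:
        """Pre-treatment scaling for a status in {naive, pretreated, possibly_pretreated}."""
        if pretreatment == "naive":
            return self.alpha_naive
        if pretreatment == "pretreated":
            return self.alpha_pretreated
        if pretreatment == "possibly_pretreated":
            return (
                self.alpha_pretreated
                if self.alpha_possibly is None
                else self.alpha_possibly
            )
        raise ValueError(f"unknown pretreatment status: {pretreatment!r}")

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        vals = {
            k: v
            for k, v in asdict(self).items()
            if v is not None
        }
        for k, v in vals.items():
            if not math.isfinite(v):
                raise ValueError(f"parameter {k} is not finite: {v}")
        if not (0.0 < self.g_ss <= 100.0):
            raise ValueError(f"g_ss must be in (0, 100], got {self.g_ss}")
        if self.k_out <= 0:
            raise ValueError(f"k_out must be > 0, got {self.k_out}")
        if self.ec50 <= 0:
            raise ValueError(f"ec50 must be > 0, got {self.ec50}")
        if self.k_emax < 0:
            raise ValueError(f"k_emax must be >= 0, got {self.k_emax}")
        if self.k_drug <= 0:
            raise ValueError(f"k_drug must be > 0, got {self.k_drug}")
        if self.emax0_ss <= 0:
            raise ValueError(f"emax0_ss must be > 0, got {self.emax0_ss}")
        for status in ("naive", "pretreated", "possibly_pretreated"):
            a = self.alpha_for(status)
            if self.emax0_ss + a * self.d_emax0 < 0:
                raise ValueError(
                    f"emax0_ss + alpha*d_emax0 < 0 for status {status!r}"
                )

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        return cls(**{k: d[k] for k in cls.__dataclass_fields__ if k in d})

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ModelParameters":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def with_(self, **kwargs) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


#: Repo-default parameter set (pilot-calibrated, not study estimates).
DEFAULT_PARAMETERS = ModelParameters()
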