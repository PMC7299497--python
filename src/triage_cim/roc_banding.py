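"""Likelihood-ratio banding of an ideal binormal ROC curve.

A test readout (bacterial infection, viral infection, or 30-day mortality
risk) is summarized by a single AUROC. The readout is modeled with the
equal-variance binormal family: scores of condition-negative patients follow
a standard normal, scores of condition-positive patients follow a normal
shifted by the separation d' = sqrt(2) * Phi^-1(AUROC). The score axis is
cut into reporting bands (low / moderate / high for 3-band readouts, low /
high for 2-band) at the points where the *band* likelihood ratio

    LR(band) = P(score in band | positive) / P(score in band | negative)

hits preset rule-out / rule-in targets (0.1 for the low band, 10 for the
high band by default). A more discriminating readout (higher AUROC) places
more of the population in the actionable low/high bands and less in the
noninformative moderate band; that reallocation is the entire mechanism of
the downstream cost model.

The band LR of the low band equals the classical negative likelihood ratio
(1 - sens)/spec of the low cutoff, and the high band's equals the positive
likelihood ratio sens/(1 - spec) of the high cutoff. A point (density-ratio)
interpretation of the targets is available behind ``convention="point"`` for
exploration; it gives closed-form cutoffs c = ln(LR)/d' + d'/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

__all__ = [
    "ReadoutSpec",
    "BandProfile",
    "InfeasibleBandsError",
    "dprime_from_auc",
    "solve_band_cutoffs",
    "band_fraction_actionable",
    "profile_table",
    "BAND_NAMES_3",
    "BAND_NAMES_2",
]

BAND_NAMES_3 = ("low", "moderate", "high")
BAND_NAMES_2 = ("low", "high")

#: absolute tolerance on |achieved band LR - target| after root finding
LR_TOL = 1e-9
#: cutoff solver tolerance
CUTOFF_XTOL = 1e-12
#: geometric bracket expansion limit for the cutoff search. Low-band cutoffs
#: drift to roughly ln(lr_low)/d' as AUROC -> 0.5, so weak but valid readouts
#: (AUROC ~ 0.55, d' ~ 0.18) need brackets beyond +/-12.
BRACKET_LIMIT = 20.0


class InfeasibleBandsError(ValueError):
    """Raised when the solved cutoffs would give overlapping bands."""


@dataclass(frozen=True)
class ReadoutSpec:
    """One test readout: its discrimination and banding targets.

    Parameters
    ----------
    name:
        Readout label, conventionally ``bacterial``, ``viral`` or
        ``mortality``.
    auroc:
        Area under the ROC curve, in the open interval (0.5, 1).
    n_bands:
        3 for low/moderate/high reporting, 2 for a single rule-in cutoff
        (low/high) as used for the viral readout.
    lr_low:
        Target band likelihood ratio of the low (rule-out) band; must be < 1.
        Ignored for 2-band readouts.
    lr_high:
        Target band likelihood ratio of the high (rule-in) band; must be > 1.
    """

    name: str
    auroc: float
    n_bands: int = 3
    lr_low: float = 0.1
    lr_high: float = 10.0

    def __post_init__(self) -> None:
        if not (0.5 < self.auroc < 1.0):
            raise ValueError(
                f"readout {self.name!r}: auroc must lie strictly between 0.5 "
                f"and 1 (got {self.auroc}); an AUROC of exactly 0.5 is an "
                "uninformative test whose bands degenerate"
            )
        if self.n_bands not in (2, 3):
            raise ValueError(f"readout {self.name!r}: n_bands must be 2 or 3")
        if not (0.0 < self.lr_low < 1.0 < self.lr_high):
            raise ValueError(
                f"readout {self.name!r}: need lr_low < 1 < lr_high "
                f"(got {self.lr_low}, {self.lr_high})"
            )

    @property
    def band_names(self) -> tuple[str, ...]:
        return BAND_NAMES_3 if self.n_bands == 3 else BAND_NAMES_2


@dataclass(frozen=True)
class BandProfile:
    """Solved banding of one readout.

    ``p_band_given_positive`` / ``p_band_given_negative`` are probability
    vectors over the bands ordered low -> high; ``achieved_lr`` is their
    elementwise ratio.
    """

    spec: ReadoutSpec
    d_prime: float
    cutoffs: tuple[float, ...]
    p_band_given_positive: np.ndarray = field(repr=False)
    p_band_given_negative: np.ndarray = field(repr=False)
    achieved_lr: np.ndarray = field(repr=False)

    @property
    def band_names(self) -> tuple[str, ...]:
        return self.spec.band_names

    def moderate_mass(self, prevalence: float) -> float:
        """Prevalence-weighted probability of the noninformative band (0 for
        2-band readouts, which have no moderate band)."""
        if self.spec.n_bands == 2:
            return 0.0
        return float(
            prevalence * self.p_band_given_positive[1]
            + (1.0 - prevalence) * self.p_band_given_negative[1]
        )

    def diagnostic_report(self) -> dict[str, float]:
        """Operating characteristics of the solved cutoffs under both common
        conventions (not enforced, reported for inspection).

        ``low_band_sensitivity`` is P(score above the low cutoff | positive),
        the rule-out sensitivity; ``high_band_specificity`` is P(score below
        the high cutoff | negative), the rule-in specificity.
        """
        lo = self.cutoffs[0]
        hi = self.cutoffs[-1]
        return {
            "low_band_sensitivity": float(norm.sf(lo - self.d_prime)),
            "low_band_fraction_negatives": float(norm.cdf(lo)),
            "high_band_specificity": float(norm.cdf(hi)),
            "high_band_detection_rate": float(norm.sf(hi - self.d_prime)),
        }


def dprime_from_auc(auroc: float) -> float:
    """Binormal separation d' implied by an AUROC.

    Under the equal-variance binormal model AUROC = Phi(d'/sqrt(2)), so
    d' = sqrt(2) * Phi^-1(AUROC); strictly increasing in AUROC, 0 at 0.5.
    """
    if not (0.5 <= auroc < 1.0):
        raise ValueError(f"auroc must lie in [0.5, 1), got {auroc}")
    return float(np.sqrt(2.0) * norm.ppf(auroc))


def _solve_one(func, target: float, readout: str, which: str) -> float:
    """Bracketed root of func(c) = target with geometric bracket expansion.

    Both band-LR functions are monotone increasing in the cutoff, so a sign
    change brackets the unique root.
    """
    lo, hi = -1.0, 1.0
    f_lo, f_hi = func(lo) - target, func(hi) - target
    while f_lo * f_hi > 0.0:
        if abs(lo) >= BRACKET_LIMIT and abs(hi) >= BRACKET_LIMIT:
            raise RuntimeError(
                f"readout {readout!r}: {which} cutoff not bracketed within "
                f"|c| <= {BRACKET_LIMIT}; the LR target is unattainable at "
                "this AUROC"
            )
        lo, hi = max(2.0 * lo, -BRACKET_LIMIT), min(2.0 * hi, BRACKET_LIMIT)
        f_lo, f_hi = func(lo) - target, func(hi) - target
    return float(brentq(lambda c: func(c) - target, lo, hi, xtol=CUTOFF_XTOL))


def solve_band_cutoffs(spec: ReadoutSpec, convention: str = "band") -> BandProfile:
    """Cut the binormal score axis into bands at the readout's LR targets.

    With ``convention="band"`` (default) the low cutoff c_lo solves
    Phi(c_lo - d')/Phi(c_lo) = lr_low and the high cutoff c_hi solves
    (1 - Phi(c_hi - d'))/(1 - Phi(c_hi)) = lr_high, each to |LR - target|
    < 1e-9. With ``convention="point"`` the targets are applied to the score
    density ratio instead, c = ln(LR)/d' + d'/2 in closed form.

    2-band readouts solve only the rule-in (high) cutoff; everything below
    it is the low band.
    """
    if convention not in ("band", "point"):
        raise ValueError(f"unknown LR convention {convention!r}")
    d = dprime_from_auc(spec.auroc)

    if convention == "band":
        def lr_low_band(c: float) -> float:
            return norm.cdf(c - d) / norm.cdf(c)

        def lr_high_band(c: float) -> float:
            return norm.sf(c - d) / norm.sf(c)

        c_hi = _solve_one(lr_high_band, spec.lr_high, spec.name, "high-band")
        cutoffs = (c_hi,)
        if spec.n_bands == 3:
            c_lo = _solve_one(lr_low_band, spec.lr_low, spec.name, "low-band")
            cutoffs = (c_lo, c_hi)
    else:
        c_hi = float(np.log(spec.lr_high) / d + d / 2.0)
        cutoffs = (c_hi,)
        if spec.n_bands == 3:
            cutoffs = (float(np.log(spec.lr_low) / d + d / 2.0), c_hi)

    if spec.n_bands == 3 and cutoffs[0] >= cutoffs[1]:
        raise InfeasibleBandsError(
            f"readout {spec.name!r}: low cutoff {cutoffs[0]:.4f} >= high "
            f"cutoff {cutoffs[1]:.4f}; bands overlap at AUROC {spec.auroc} "
            f"with LR targets ({spec.lr_low}, {spec.lr_high})"
        )

    def band_masses(shift: float) -> np.ndarray:
        # tail bands via cdf/sf directly so extreme cutoffs keep relative
        # precision (cdf differences underflow beyond ~8 sigma)
        lo_mass = norm.cdf(cutoffs[0] - shift)
        hi_mass = norm.sf(cutoffs[-1] - shift)
        if len(cutoffs) == 1:
            return np.array([lo_mass, hi_mass])
        return np.array([lo_mass, max(1.0 - lo_mass - hi_mass, 0.0), hi_mass])

    p_pos = band_masses(d)
    p_neg = band_masses(0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        lr = np.where(p_neg > 0.0, p_pos / np.where(p_neg > 0, p_neg, 1.0), np.inf)
    return BandProfile(
        spec=spec,
        d_prime=d,
        cutoffs=cutoffs,
        p_band_given_positive=p_pos,
        p_band_given_negative=p_neg,
        achieved_lr=lr,
    )


def band_fraction_actionable(profile: BandProfile, prevalence: float) -> float:
    """Prevalence-weighted population mass outside the moderate band.

    This is the fraction of patients receiving an actionable (rule-in or
    rule-out) report; it grows with AUROC at fixed LR targets, which is the
    mechanism by which a more accurate test changes care.
    """
    if not (0.0 <= prevalence <= 1.0):
        raise ValueError(f"prevalence must lie in [0, 1], got {prevalence}")
    return 1.0 - profile.moderate_mass(prevalence)


def profile_table(profiles: dict[str, BandProfile]) -> pd.DataFrame:
    """Flat tabular (CSV-ready) dump of solved profiles, one row per band."""
    rows = []
    for name, prof in profiles.items():
        for i, band in enumerate(prof.band_names):
            rows.append(
                {
                    "readout": name,
                    "auroc": prof.spec.auroc,
                    "d_prime": prof.d_prime,
                    "band": band,
                    "cutoff_low": (-np.inf if i == 0 else prof.cutoffs[i - 1]),
                    "cutoff_high": (
                        np.inf if i == len(prof.band_names) - 1 else prof.cutoffs[i]
                    ),
                    "p_given_positive": prof.p_band_given_positive[i],
                    "p_given_negative": prof.p_band_given_negative[i],
                    "achieved_lr": prof.achieved_lr[i],
                }
            )
    return pd.DataFrame(rows)
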