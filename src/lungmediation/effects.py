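"""Natural direct and path-specific indirect effects.

With a linear structural system on the latent scale and no
exposure-mediator interactions, the counterfactual natural effects of an
exposure contrast reduce to path products of the structural coefficients:

* natural direct effect (NDE)            ``c``          (exposure -> outcome)
* indirect via the prepuberty-overweight
  mediator M1 only                       ``a * b1``
* indirect via adult height M2 only      ``h * b2``
* indirect via the serial chain M1->M2   ``a * d * b2``

where ``a`` is the probit path onto the latent mediator, ``h`` the linear
path onto height, and ``b1``, ``b2``, ``d`` the downstream structural
coefficients. The total effect is the exact sum of the four components --
the additivity is an algebraic identity of the linear latent-scale system,
not an approximation. The same formulas apply to both exposure contrasts
(overweight before puberty vs never; overweight at 30 but not before
puberty vs never), using that contrast's dummies.

Moderation by offspring sex is summarised by the componentwise difference
``delta = sons - daughters``, and pathways are classified by the standard
mediation typology from the significance pattern of direct and indirect
effects.
"""

from __future__ import annotations

from dataclasses import dataclass

from .coefficients import CONTRASTS, CoefficientError, PathCoefficients

#: names of the components of a decomposition, in reporting order
EFFECT_NAMES = ("nde", "nie_via_m1", "nie_via_m2", "nie_via_m1_m2", "total")

MEDIATION_CLASSES = ("complementary", "indirect_only", "direct_only", "non_mediation")


@dataclass(frozen=True)
class EffectDecomposition:
    """One contrast x group x outcome decomposition, in outcome units."""

    contrast: str
    group: str
    outcome: str
    nde: float
    nie_via_m1: float
    nie_via_m2: float
    nie_via_m1_m2: float

    @property
    def total(self) -> float:
        return self.nde + self.nie_via_m1 + self.nie_via_m2 + self.nie_via_m1_m2

    def as_dict(self) -> dict:
        return {
            "contrast": self.contrast, "group": self.group, "outcome": self.outcome,
            "nde": self.nde, "nie_via_m1": self.nie_via_m1,
            "nie_via_m2": self.nie_via_m2, "nie_via_m1_m2": self.nie_via_m1_m2,
            "total": self.total,
        }

    def value(self, effect: str) -> float:
        if effect == "total":
            return self.total
        if effect not in EFFECT_NAMES:
            raise KeyError(f"unknown effect {effect!r}")
        return getattr(self, effect)


@dataclass(frozen=True)
class GroupDifference:
    """Sons-minus-daughters difference of one effect component."""

    contrast: str
    outcome: str
    effect: str
    delta: float


def decompose_effects(coefs: PathCoefficients, contrast: str, group: str,
                      outcome: str) -> EffectDecomposition:
    """Decompose the total effect of one exposure contrast on one outcome.

    Parameters
    ----------
    coefs
        Structural coefficients of the chosen offspring-sex group.
    contrast
        ``"before_puberty_vs_never"`` or ``"at30_vs_never"``.
    group
        Label carried through to the result (``"son"`` / ``"daughter"``).
    outcome
        One of ``coefs.outcomes``.
    """
    a, h, c = coefs.exposure_paths(contrast, outcome)
    k = coefs.outcome_index(outcome)
    b1 = float(coefs.b1[k])
    b2 = float(coefs.b2[k])
    d = float(coefs.d)
    return EffectDecomposition(
        contrast=contrast, group=group, outcome=outcome,
        nde=c,
        nie_via_m1=a * b1,
        nie_via_m2=h * b2,
        nie_via_m1_m2=a * d * b2,
    )


def decompose_all(coefs_by_group: dict, outcomes=None) -> list:
    """All decompositions for every contrast x group x outcome combination."""
    out = []
    for group, coefs in coefs_by_group.items():
        names = outcomes if outcomes is not None else coefs.outcomes
        for contrast in CONTRASTS:
            for outcome in names:
                out.append(decompose_effects(coefs, contrast, group, outcome))
    return out


def total_effect(decomp: EffectDecomposition) -> float:
    """Total effect: the exact sum of the direct and indirect components.

    Equals the reduced-form exposure coefficient of a regression of the
    outcome on exposure and outcome-equation covariates.
    """
    return decomp.total


def group_difference(sons: EffectDecomposition,
                     daughters: EffectDecomposition) -> dict:
    """Componentwise sons-minus-daughters moderation contrasts.

    Returns a mapping effect-name -> :class:`GroupDifference` for the five
    components of matching decompositions.
    """
    if (sons.contrast, sons.outcome) != (daughters.contrast, daughters.outcome):
        raise CoefficientError(
            "mismatched decompositions: "
            f"({sons.contrast}, {sons.outcome}) vs ({daughters.contrast}, {daughters.outcome})")
    return {
        name: GroupDifference(contrast=sons.contrast, outcome=sons.outcome,
                              effect=name,
                              delta=sons.value(name) - daughters.value(name))
        for name in EFFECT_NAMES
    }


def classify_mediation(direct_sig: bool, indirect_sig: bool,
                       same_sign: bool) -> str:
    """Mediation typology from bootstrap significance flags.

    complementary : direct and indirect both significant, same sign
    indirect_only : only the indirect effect significant
    direct_only   : only the direct effect significant
    non_mediation : anything else (neither significant, or both significant
                    with opposite signs)
    """
    if direct_sig and indirect_sig and same_sign:
        return "complementary"
    if indirect_sig and not direct_sig:
        return "indirect_only"
    if direct_sig and not indirect_sig:
        return "direct_only"
    return "non_mediation"
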