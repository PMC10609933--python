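"""Published release parameters for levofloxacin-loaded zein gel depots.

Four formulations of levofloxacin HCl (Lv, 1% w/w) in zein dissolved in
dimethyl sulfoxide (D) or glycerol formal (G) at 20% or 25% w/w polymer,
released into 80 mL of pH 6.8 phosphate buffer.  For each formulation two
estimates of the transfer coefficient ``K32`` (day^-1 convention,
``K32 = rate_a * V3``) and the matrix-edge plateau ``C2_edge`` (% of dose)
are tabulated, one per numerical differentiation scheme used in the
estimation: the 2-point forward formula (order h) and the 5-point central
formula (order h^4).  The corresponding fitted release equations are
single exponentials with rate constant ``K32 / 80`` day^-1.

These values serve as reference ground truths for regeneration tests: a
dataset produced from a row's release equation, re-fitted with the row's
scheme, must return the row's parameters.
"""

from __future__ import annotations

from .release_core import FirstOrderModel

__all__ = [
    "FORWARD",
    "CENTRAL4",
    "REFERENCE_PARAMETERS",
    "reference_model",
]

#: method tag for the 2-point forward difference scheme, order h
FORWARD = "forward"
#: method tag for the 5-point central difference scheme, order h^4
CENTRAL4 = "central4"

#: (formulation label, scheme) -> (K32 [day^-1 convention], C2_edge [% dose])
#: with bath volume V3 = 80 mL throughout.
REFERENCE_PARAMETERS: dict[tuple[str, str], tuple[float, float]] = {
    ("Lv20ZD", FORWARD): (56.65, 103.50),
    ("Lv20ZD", CENTRAL4): (52.91, 105.50),
    ("Lv25ZD", FORWARD): (51.57, 88.97),
    ("Lv25ZD", CENTRAL4): (64.76, 88.60),
    ("Lv20ZG", FORWARD): (47.58, 98.35),
    ("Lv20ZG", CENTRAL4): (32.55, 104.50),
    ("Lv25ZG", FORWARD): (34.47, 74.01),
    ("Lv25ZG", CENTRAL4): (50.23, 71.58),
}

#: bath volume used for every tabulated formulation, mL
V3_REFERENCE = 80.0


def reference_model(label: str, method: str) -> FirstOrderModel:
    """Reference release model for a (formulation, scheme) pair.

    The returned model has ``rate_a = K32 / 80`` and ``t0 = 0`` — the
    fitted release equation for that row.
    """
    try:
        k32, c2 = REFERENCE_PARAMETERS[(label, method)]
    except KeyError:
        known = sorted({lab for lab, _ in REFERENCE_PARAMETERS})
        raise KeyError(
            f"unknown formulation/method pair ({label!r}, {method!r}); "
            f"formulations: {known}, methods: [{FORWARD!r}, {CENTRAL4!r}]"
        ) from None
    return FirstOrderModel.from_K32(K32=k32, C2_edge=c2, V3=V3_REFERENCE, t0=0.0)
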