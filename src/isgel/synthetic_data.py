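"""Cup-method release dataset generation with known ground truth.

The cup method places 0.4 g of formulation (1% w/w drug, i.e. a 4 mg
nominal dose) in a porcelain cup immersed in 80 mL of pH 6.8 phosphate
buffer at 37 degC.  At each sampling time a 5 mL aliquot of the medium is
withdrawn for assay and replaced with fresh buffer, so the measured
medium concentration at sample ``n`` reflects both the drug released so
far and the drug removed in earlier aliquots:

    c_n = (A_n - Vs * sum_{i<n} c_i) / V3

where ``A_n`` is the true cumulative mass released by sample ``n``.  The
standard cumulative-percent correction inverts this exactly:

    A_n = c_n * V3 + Vs * sum_{i<n} c_i,   percent_n = 100 A_n / dose.

Measurement noise (a stand-in for spectrophotometric assay error) is
applied to the medium concentrations — the quantity actually measured —
so that it propagates through the correction formula the same way real
assay error would.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

from .errors import ConfigurationError, InvalidInputError
from .release_core import FirstOrderModel, ReleaseSeries, evaluate_release_curve

__all__ = [
    "CupProtocol",
    "NoiseSpec",
    "apply_cup_sampling",
    "reconstruct_cumulative",
    "corrupt_with_noise",
    "make_dataset",
    "DEFAULT_SCHEDULE",
]

#: default sampling schedule, days (12 h to 7 days)
DEFAULT_SCHEDULE: tuple[float, ...] = (0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0)


@dataclass(frozen=True)
class CupProtocol:
    """Cup-method release protocol.

    Defaults reproduce the reference experiment: 80 mL medium, 5 mL
    aliquots replaced with fresh buffer, 4 mg nominal dose (0.4 g of
    formulation at 1% w/w drug), sampled from 12 h to 7 days.
    """

    V3: float = 80.0
    Vs: float = 5.0
    dose_mg: float = 4.0
    schedule: tuple[float, ...] = DEFAULT_SCHEDULE

    def __post_init__(self) -> None:
        if not (0 < self.Vs < self.V3):
            raise ConfigurationError(
                f"need 0 < Vs < V3, got Vs={self.Vs}, V3={self.V3}"
            )
        if not (self.dose_mg > 0):
            raise ConfigurationError(f"dose_mg must be > 0, got {self.dose_mg}")
        sched = np.asarray(self.schedule, dtype=float)
        if sched.size == 0 or (sched.size > 1 and not np.all(np.diff(sched) > 0)):
            raise ConfigurationError("schedule must be nonempty, strictly increasing")


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise description for medium concentrations.

    ``kind='none'`` leaves data untouched.  ``'additive-normal'`` adds
    N(0, sd^2) in concentration units (mg/mL); ``'multiplicative-normal'``
    multiplies by ``1 + N(0, sd^2)`` (sd is a relative fraction).  Values
    are deliberately not clipped: negative concentrations can occur and
    are left visible, as they would be in a real assay near the detection
    limit.
    """

    kind: Literal["none", "additive-normal", "multiplicative-normal"] = "none"
    sd: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in ("none", "additive-normal", "multiplicative-normal"):
            raise ConfigurationError(f"unknown noise kind {self.kind!r}")
        if self.sd < 0:
            raise ConfigurationError(f"sd must be >= 0, got {self.sd}")
        if self.kind != "none" and self.seed is None:
            raise ConfigurationError(
                "a seed is required for stochastic noise kinds"
            )


def apply_cup_sampling(
    cumulative_mg: Sequence[float], protocol: CupProtocol
) -> np.ndarray:
    """Medium concentrations (mg/mL) observed at each scheduled sample.

    ``cumulative_mg[n]`` is the true cumulative mass released by sample
    ``n``; aliquot removal in earlier samples depletes the medium, giving
    ``c_n = (A_n - Vs * sum_{i<n} c_i) / V3``.
    """
    a = np.asarray(cumulative_mg, dtype=float)
    if a.size > 1 and np.any(np.diff(a) < 0):
        raise InvalidInputError("cumulative released mass must be nondecreasing")
    if a.size and a[0] < 0:
        raise InvalidInputError("cumulative released mass must be nonnegative")
    c = np.empty_like(a)
    removed = 0.0  # mass carried away by previous aliquots, mg
    for n in range(a.size):
        c[n] = (a[n] - removed) / protocol.V3
        removed += protocol.Vs * c[n]
    return c


def reconstruct_cumulative(
    concentrations: Sequence[float], protocol: CupProtocol
) -> ReleaseSeries:
    """Cumulative release (% of dose) from sampled medium concentrations.

    Exact algebraic inverse of :func:`apply_cup_sampling`:
    ``A_n = c_n V3 + Vs sum_{i<n} c_i``, expressed as percent of dose on
    the protocol's schedule.
    """
    c = np.asarray(concentrations, dtype=float)
    if c.size != len(protocol.schedule):
        raise InvalidInputError(
            f"got {c.size} concentrations for a schedule of "
            f"{len(protocol.schedule)} samples"
        )
    prior = np.concatenate([[0.0], np.cumsum(c)[:-1]])
    a = c * protocol.V3 + protocol.Vs * prior
    percent = 100.0 * a / protocol.dose_mg
    return ReleaseSeries(
        times=np.asarray(protocol.schedule, dtype=float),
        values=percent,
        t0=0.0,
    )


def corrupt_with_noise(
    concentrations: Sequence[float], noise: NoiseSpec
) -> np.ndarray:
    """Apply measurement noise to medium concentrations.

    Deterministic for a fixed seed; the identity for ``kind='none'`` or
    ``sd=0``.
    """
    c = np.asarray(concentrations, dtype=float)
    if noise.kind == "none" or noise.sd == 0.0:
        return c.copy()
    rng = np.random.default_rng(noise.seed)
    draws = rng.normal(0.0, noise.sd, size=c.shape)
    if noise.kind == "additive-normal":
        return c + draws
    return c * (1.0 + draws)


def make_dataset(
    model: FirstOrderModel,
    protocol: CupProtocol,
    noise: NoiseSpec = NoiseSpec(),
) -> tuple[ReleaseSeries, ReleaseSeries, dict]:
    """Generate a (truth, observed) cup-method dataset pair.

    The truth series is the closed-form release curve sampled on the
    protocol schedule.  The observed series is obtained by converting to
    released mass, passing through the aliquot-depletion model, adding
    measurement noise to the per-sample medium concentrations, and
    applying the standard cumulative correction — exactly the path a real
    measurement takes.  With no noise, observed equals truth to round-off.

    Returns ``(truth, observed, metadata)`` where ``metadata`` records
    every generator parameter and the noise seed.
    """
    truth = evaluate_release_curve(model, protocol.schedule)
    cumulative_mg = truth.values / 100.0 * protocol.dose_mg
    concs = apply_cup_sampling(cumulative_mg, protocol)
    noisy = corrupt_with_noise(concs, noise)
    observed = reconstruct_cumulative(noisy, protocol)
    metadata = {
        "C2_edge_pct": model.C2_edge,
        "rate_a_per_day": model.rate_a,
        "K32_per_day": model.K32,
        "V3_mL": protocol.V3,
        "Vs_mL": protocol.Vs,
        "dose_mg": protocol.dose_mg,
        "t0_days": model.t0,
        "noise_kind": noise.kind,
        "noise_sd": noise.sd,
        "noise_seed": noise.seed,
    }
    return truth, observed, metadata
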