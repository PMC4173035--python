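"""Genotype scenarios: named parameter transformations of the wild-type
clock and their predicted phenotypes.

* ``knockin_scenario`` — intron knock-in alleles that enlarge the *Hes7*
  transcription unit by 5, 10 or 20 kb, lengthening the transcriptional
  delay by insert-length / polymerase-velocity.
* ``utr_loss_scenario`` — loss of the 3'UTR through premature termination:
  mRNA output reduced (measured at 30%) and translation impaired, damping
  or arresting the oscillation with uniformly elevated mRNA.
* ``intron_deletion_scenario`` — removal of intronic delay from the
  endogenous gene; a severe reduction (19 min) abolishes oscillation while
  a mild one (5 min) shortens the period.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

from .delays import (
    HES7_GENE_LENGTH_KB,
    POLYMERASE_SLOW_KB_PER_MIN,
    GeneArchitecture,
    delay_budget,
)
from .errors import InvalidParameterError
from .metrics import (
    DEFAULT_BURN_IN_MIN,
    OscillationMetrics,
    trajectory_metrics,
)
from .model import WILD_TYPE, ClockParameters, Trajectory, integrate

__all__ = [
    "ScenarioResult",
    "wild_type_scenario",
    "knockin_scenario",
    "utr_loss_scenario",
    "intron_deletion_scenario",
    "run_named_scenario",
    "SCENARIO_NAMES",
]

#: Delay reductions (min) for the intron-deletion comparators: full intronic
#: delay and the two-of-three-introns deletion.
INTRON_DELAY_FULL_MIN = 19.0
INTRON_DELAY_MILD_MIN = 5.0

_NUMERICS = {"t_end": 2400.0, "dt": 0.05}


@dataclass
class ScenarioResult:
    """Outcome of one scenario run against the wild-type baseline."""

    name: str
    overrides: dict
    params: ClockParameters
    metrics: OscillationMetrics
    period_change_min: float
    phenotype_note: str
    trajectory: Trajectory = field(repr=False, default=None)

    def to_json(self, indent: int | None = 2) -> str:
        payload = {
            "name": self.name,
            "overrides": self.overrides,
            "params_fingerprint": self.params.fingerprint(),
            "metrics": self.metrics.as_dict(),
            "period_change_min": self.period_change_min,
            "phenotype_note": self.phenotype_note,
        }
        return json.dumps(payload, indent=indent, sort_keys=True)


def _run(
    name: str,
    params: ClockParameters,
    overrides: dict,
    note: str,
    baseline: ClockParameters,
    channel: str = "mrna",
    burn_in_min: float = DEFAULT_BURN_IN_MIN,
) -> ScenarioResult:
    traj = integrate(params, **_NUMERICS)
    m = trajectory_metrics(traj, channel=channel, burn_in_min=burn_in_min)
    base_traj = integrate(baseline, **_NUMERICS)
    base_m = trajectory_metrics(base_traj, channel=channel, burn_in_min=burn_in_min)
    if math.isnan(m.period_min) or math.isnan(base_m.period_min):
        change = math.nan
    else:
        change = m.period_min - base_m.period_min
    return ScenarioResult(
        name=name,
        overrides=overrides,
        params=params,
        metrics=m,
        period_change_min=change,
        phenotype_note=note,
        trajectory=traj,
    )


def wild_type_scenario(
    baseline: ClockParameters = WILD_TYPE,
) -> ScenarioResult:
    """The unperturbed baseline: sustained ~2-h oscillation."""
    return _run(
        "wild-type",
        baseline,
        overrides={},
        note="sustained oscillation with a ~2-h period; cyclic wave "
        "pattern in the PSM",
        baseline=baseline,
    )


def knockin_scenario(
    insert_kb: float,
    speed_kb_per_min: float = POLYMERASE_SLOW_KB_PER_MIN,
    baseline: ClockParameters = WILD_TYPE,
) -> ScenarioResult:
    """Intron knock-in enlarging the transcription unit by ``insert_kb``.

    The model's prediction for a correctly spliced insert: oscillation stays
    sustained and the period lengthens with the extra transcription time.
    """
    arch = GeneArchitecture(
        base_length_kb=HES7_GENE_LENGTH_KB,
        insert_length_kb=insert_kb,
        polymerase_speed_kb_per_min=speed_kb_per_min,
    )
    budget = delay_budget(arch, baseline.delay)
    params = baseline.with_delay(budget)
    extra = budget.total_min - baseline.delay.total_min
    return _run(
        f"knockin-{insert_kb:g}k",
        params,
        overrides={
            "insert_kb": insert_kb,
            "speed_kb_per_min": speed_kb_per_min,
            "extra_delay_min": extra,
        },
        note="model prediction for a spliced insert: sustained oscillation "
        f"with the period lengthened by the +{extra:.2f} min delay",
        baseline=baseline,
    )


def utr_loss_scenario(
    mrna_output_scale: float = 0.7,
    translation_scale: float = 1.0,
    baseline: ClockParameters = WILD_TYPE,
) -> ScenarioResult:
    """3'UTR loss: reduced mRNA output and (optionally) impaired translation.

    The 30% mRNA reduction is implemented as reduced effective synthesis
    (``mrna_output_scale=0.7``).  Severe translation loss collapses the
    repressive feedback: mRNA settles high and uniform and the oscillation
    is no longer sustained — the knock-in in situ phenotype.
    """
    if not (0.0 <= mrna_output_scale <= 1.0 and 0.0 <= translation_scale <= 1.0):
        raise InvalidParameterError("scales must lie in [0, 1]")
    params = replace(
        baseline,
        mrna_synthesis_max=baseline.mrna_synthesis_max * mrna_output_scale,
        protein_synthesis=baseline.protein_synthesis * translation_scale,
    )
    return _run(
        "utr-loss",
        params,
        overrides={
            "mrna_output_scale": mrna_output_scale,
            "translation_scale": translation_scale,
        },
        note="3'UTR loss: mRNA output scaled to "
        f"{mrna_output_scale:g}, translation to {translation_scale:g}; "
        "severe translation loss predicts damped/arrested dynamics with "
        "uniformly elevated mRNA",
        baseline=baseline,
    )


def intron_deletion_scenario(
    delay_reduction_min: float,
    baseline: ClockParameters = WILD_TYPE,
) -> ScenarioResult:
    """Shorten the mRNA-side delay by ``delay_reduction_min`` minutes.

    The reduction is taken from the processing component first (splicing
    dominates the intronic delay), then from transcription.
    """
    if delay_reduction_min < 0:
        raise InvalidParameterError("delay reduction must be >= 0")
    params = baseline.with_added_delay(-delay_reduction_min)
    return _run(
        f"intron-del-{delay_reduction_min:g}",
        params,
        overrides={"delay_reduction_min": delay_reduction_min},
        note="intron deletion: severe delay reduction abolishes the "
        "oscillation, mild reduction shortens the period",
        baseline=baseline,
    )


#: Named presets exposed on the command line.
SCENARIO_NAMES = (
    "wild-type",
    "knockin-5k",
    "knockin-10k",
    "knockin-20k",
    "utr-loss",
    "intron-del-5",
    "intron-del-19",
)


def run_named_scenario(
    name: str,
    speed_kb_per_min: float = POLYMERASE_SLOW_KB_PER_MIN,
    mrna_output_scale: float = 0.7,
    translation_scale: float = 0.05,
    baseline: ClockParameters = WILD_TYPE,
) -> ScenarioResult:
    """Dispatch one of :data:`SCENARIO_NAMES`."""
    if name == "wild-type":
        return wild_type_scenario(baseline)
    if name.startswith("knockin-"):
        insert = float(name.removeprefix("knockin-").removesuffix("k"))
        return knockin_scenario(insert, speed_kb_per_min, baseline)
    if name == "utr-loss":
        return utr_loss_scenario(mrna_output_scale, translation_scale, baseline)
    if name.startswith("intron-del-"):
        reduction = float(name.removeprefix("intron-del-"))
        return intron_deletion_scenario(reduction, baseline)
    raise InvalidParameterError(
        f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}"
    )
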