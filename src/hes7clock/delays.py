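"""Delay-budget arithmetic for the Hes7 negative-feedback loop.

The total feedback delay tau is the time from the start of *Hes7*
transcription to the accumulation of functional repressor protein.  It is
decomposed into three additive components:

* transcription — RNA polymerase II traversal of the transcription unit,
  ``length / velocity``;
* processing — splicing and nuclear export of the mRNA;
* translation — protein synthesis and maturation.

Enlarging the transcription unit (an intron knock-in) adds
``insert_length / velocity`` to the transcription component and leaves the
other components untouched.  Published elongation-rate estimates for RNA
polymerase II span 1.1–4.8 kb/min; both ends are carried as named presets
and no single velocity is privileged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .errors import InvalidParameterError

#: Slow and fast ends of the published RNA polymerase II elongation-rate
#: range, kb/min.
POLYMERASE_SLOW_KB_PER_MIN = 1.1
POLYMERASE_FAST_KB_PER_MIN = 4.8

#: Length of the unmodified mouse Hes7 transcription unit, kb.
HES7_GENE_LENGTH_KB = 2.8


def round_sig_figs(x: float, sig_figs: int) -> float:
    """Round ``x`` to ``sig_figs`` significant figures."""
    if sig_figs < 1:
        raise InvalidParameterError(f"sig_figs must be >= 1, got {sig_figs}")
    if x == 0:
        return 0.0
    return round(x, sig_figs - 1 - math.floor(math.log10(abs(x))))


def transcription_time(
    length_kb: float,
    speed_kb_per_min: float,
    sig_figs: int | None = None,
) -> float:
    """Time (min) for RNA polymerase to transcribe ``length_kb`` at
    ``speed_kb_per_min``.

    With ``sig_figs`` given, the quotient is rounded to that many
    significant figures (e.g. a 5 kb insert at 1.1 kb/min is 4.5 min at two
    significant figures); with ``sig_figs`` omitted the exact quotient is
    returned.
    """
    if speed_kb_per_min <= 0:
        raise InvalidParameterError(
            f"polymerase speed must be positive, got {speed_kb_per_min}"
        )
    if length_kb < 0:
        raise InvalidParameterError(f"length must be >= 0, got {length_kb}")
    t = length_kb / speed_kb_per_min
    if sig_figs is None:
        return t
    return round_sig_figs(t, sig_figs)


@dataclass(frozen=True)
class DelayBudget:
    """Decomposition of the total feedback delay into additive components.

    All components are in minutes and non-negative.  ``total_min`` is always
    the exact sum of the three components.
    """

    transcription_min: float
    processing_min: float
    translation_min: float

    def __post_init__(self) -> None:
        for name in ("transcription_min", "processing_min", "translation_min"):
            v = getattr(self, name)
            if not (v >= 0):
                raise InvalidParameterError(f"{name} must be >= 0, got {v}")

    @property
    def total_min(self) -> float:
        return self.transcription_min + self.processing_min + self.translation_min

    @property
    def mrna_side_min(self) -> float:
        """Delay on the mRNA equation: transcription plus processing."""
        return self.transcription_min + self.processing_min

    @property
    def protein_side_min(self) -> float:
        """Delay on the protein equation: translation."""
        return self.translation_min

    def as_dict(self) -> dict[str, float]:
        return {
            "transcription_min": self.transcription_min,
            "processing_min": self.processing_min,
            "translation_min": self.translation_min,
            "total_min": self.total_min,
        }


@dataclass(frozen=True)
class GeneArchitecture:
    """Physical description of a (possibly modified) transcription unit."""

    base_length_kb: float
    insert_length_kb: float = 0.0
    polymerase_speed_kb_per_min: float = POLYMERASE_SLOW_KB_PER_MIN
    extra_processing_delay_min: float = 0.0

    def __post_init__(self) -> None:
        if self.base_length_kb < 0:
            raise InvalidParameterError("base_length_kb must be >= 0")
        if self.insert_length_kb < 0:
            raise InvalidParameterError("insert_length_kb must be >= 0")
        if self.polymerase_speed_kb_per_min <= 0:
            raise InvalidParameterError("polymerase_speed_kb_per_min must be > 0")
        if self.extra_processing_delay_min < 0:
            raise InvalidParameterError("extra_processing_delay_min must be >= 0")

    @property
    def total_length_kb(self) -> float:
        return self.base_length_kb + self.insert_length_kb


def delay_budget(arch: GeneArchitecture, baseline: DelayBudget) -> DelayBudget:
    """Delay budget of a modified allele, relative to ``baseline``.

    The insert's contribution is attributed entirely to the transcription
    component (the insert lengthens the transcribed unit; translation is
    unchanged), plus any declared extra processing time.
    """
    dt_transcription = transcription_time(
        arch.insert_length_kb, arch.polymerase_speed_kb_per_min
    )
    return replace(
        baseline,
        transcription_min=baseline.transcription_min + dt_transcription,
        processing_min=baseline.processing_min + arch.extra_processing_delay_min,
    )
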