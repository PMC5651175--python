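"""Arm-level copy-number alteration calling and chromosomal-instability labels.

A chromosome arm counts as altered when segments at |log2 copy ratio|
>= 0.15 cover at least 80% of the arm (both comparisons inclusive).
A sample is labelled SCNA-high (chromosomally unstable) when it carries
at least one arm-level *loss* outside an exclusion list — by default
18p, 18q, 21p and 21q, arms recurrently lost in both stable and
unstable tumours and therefore uninformative.  Gains never qualify.

Fractions are base-pair weighted: the denominator is the full arm
length, so arm bases not covered by any segment count toward neither
gain nor loss.  Probe weighting is available via ``weight="probes"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import ArmDefinition, SegmentedCopyNumberProfile

__all__ = [
    "ArmCall",
    "CINCall",
    "DEFAULT_EXCLUDED_ARMS",
    "project_segments_to_arm",
    "call_arm",
    "classify_cin",
    "cohort_cin",
]

DEFAULT_EXCLUDED_ARMS = frozenset({"18p", "18q", "21p", "21q"})

DEFAULT_LOG2_THRESHOLD = 0.15
DEFAULT_ALTERED_FRACTION = 0.80


@dataclass(frozen=True)
class ArmCall:
    arm_name: str
    fraction_gain: float
    fraction_loss: float
    call: str  # gain | loss | neutral | not_callable

    def __post_init__(self) -> None:
        if self.fraction_gain + self.fraction_loss > 1 + 1e-9:
            raise ValueError("gain and loss fractions sum above 1")


@dataclass
class CINCall:
    sample_id: str
    label: str  # SCNA_high | SCNA_low
    qualifying_arm_losses: list[str] = field(default_factory=list)
    excluded_arm_losses: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        expected = "SCNA_high" if self.qualifying_arm_losses else "SCNA_low"
        if self.label != expected:
            raise ValueError("label inconsistent with qualifying arm losses")


def project_segments_to_arm(
    profile: SegmentedCopyNumberProfile,
    arm: ArmDefinition,
    gain_threshold: float = DEFAULT_LOG2_THRESHOLD,
    loss_threshold: float = DEFAULT_LOG2_THRESHOLD,
    weight: str = "bases",
) -> tuple[float, float]:
    """Fractions of the arm covered by gained / lost segments.

    ``fraction_loss`` is the summed intersection length of segments with
    log2 <= -loss_threshold with the arm interval, divided by the full
    arm length (``fraction_gain`` analogous with log2 >= +gain_threshold).
    With ``weight="probes"`` the n_probes field replaces base-pair
    length (segments lacking probe counts fall back to length weights
    are an error in that mode).
    """
    if gain_threshold <= 0 or loss_threshold <= 0:
        raise ValueError("thresholds must be positive log2 magnitudes")
    if arm.length <= 0:
        raise ValueError(f"arm {arm.arm_name} has non-positive length")
    if weight not in ("bases", "probes"):
        raise ValueError("weight must be 'bases' or 'probes'")

    gain = 0.0
    loss = 0.0
    denom = 0.0
    for seg in profile.segments:
        if seg.chromosome != arm.chromosome:
            continue
        ov = min(seg.end, arm.end) - max(seg.start, arm.start)
        if ov <= 0:
            continue
        if weight == "probes":
            if seg.n_probes is None:
                raise ValueError("probe weighting requested but segment lacks n_probes")
            w = seg.n_probes * (ov / seg.length)
        else:
            w = float(ov)
        denom += w
        if seg.log2_ratio >= gain_threshold:
            gain += w
        elif seg.log2_ratio <= -loss_threshold:
            loss += w
    if weight == "bases":
        denom = float(arm.length)  # uncovered bases stay in the denominator
    if denom == 0:
        return 0.0, 0.0
    return gain / denom, loss / denom


def call_arm(
    fractions: tuple[float, float],
    arm: ArmDefinition | None = None,
    altered_fraction_threshold: float = DEFAULT_ALTERED_FRACTION,
) -> ArmCall:
    """Turn (fraction_gain, fraction_loss) into a gain/loss/neutral call.

    Comparisons are inclusive (>=): a fraction of exactly 0.80 calls the
    arm altered.  An arm marked non-callable returns ``not_callable``.
    """
    fraction_gain, fraction_loss = fractions
    name = arm.arm_name if arm is not None else ""
    if arm is not None and not arm.callable:
        return ArmCall(name, fraction_gain, fraction_loss, "not_callable")
    gain_hit = fraction_gain >= altered_fraction_threshold
    loss_hit = fraction_loss >= altered_fraction_threshold
    if gain_hit and loss_hit:
        raise ValueError(
            f"arm {name or '?'}: both gain and loss exceed the altered-fraction "
            f"threshold {altered_fraction_threshold}; threshold must exceed 0.5"
        )
    call = "gain" if gain_hit else "loss" if loss_hit else "neutral"
    return ArmCall(name, fraction_gain, fraction_loss, call)


def classify_cin(
    arm_calls: list[ArmCall],
    excluded_arms: frozenset[str] | set[str] = DEFAULT_EXCLUDED_ARMS,
    sample_id: str = "",
) -> CINCall:
    """SCNA-high iff >= 1 arm-level loss outside the exclusion list."""
    names = [c.arm_name for c in arm_calls]
    if len(set(names)) != len(names):
        raise ValueError("duplicate arm names in arm calls")
    qualifying = [c.arm_name for c in arm_calls
                  if c.call == "loss" and c.arm_name not in excluded_arms]
    excluded = [c.arm_name for c in arm_calls
                if c.call == "loss" and c.arm_name in excluded_arms]
    label = "SCNA_high" if qualifying else "SCNA_low"
    return CINCall(sample_id, label, qualifying, excluded)


def cohort_cin(
    profiles: list[SegmentedCopyNumberProfile],
    arm_table: list[ArmDefinition],
    gain_threshold: float = DEFAULT_LOG2_THRESHOLD,
    loss_threshold: float = DEFAULT_LOG2_THRESHOLD,
    altered_fraction_threshold: float = DEFAULT_ALTERED_FRACTION,
    excluded_arms: frozenset[str] | set[str] = DEFAULT_EXCLUDED_ARMS,
    weight: str = "bases",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify every sample and tabulate per-arm alteration frequencies.

    Returns ``(calls, arm_frequencies)``:

    * ``calls`` — one row per sample: sample, label, qualifying and
      excluded arm losses, number of arm gains/losses;
    * ``arm_frequencies`` — one row per callable arm: gain and loss
      frequency across the cohort.
    """
    rows = []
    freq: dict[str, dict[str, int]] = {
        a.arm_name: {"gain": 0, "loss": 0} for a in arm_table if a.callable
    }
    n = len(profiles)
    for prof in profiles:
        arm_calls = []
        for arm in arm_table:
            fr = project_segments_to_arm(prof, arm, gain_threshold,
                                         loss_threshold, weight)
            ac = call_arm(fr, arm, altered_fraction_threshold)
            arm_calls.append(ac)
            if ac.call in ("gain", "loss"):
                freq[ac.arm_name][ac.call] += 1
        cin = classify_cin(arm_calls, excluded_arms, prof.sample_id)
        rows.append({
            "sample": prof.sample_id,
            "label": cin.label,
            "qualifying_arm_losses": ",".join(cin.qualifying_arm_losses),
            "excluded_arm_losses": ",".join(cin.excluded_arm_losses),
            "n_arm_gains": sum(c.call == "gain" for c in arm_calls),
            "n_arm_losses": sum(c.call == "loss" for c in arm_calls),
        })
    calls = pd.DataFrame(rows).set_index("sample")
    arm_freq = pd.DataFrame(
        [{"arm": a, "gain_freq": v["gain"] / n if n else np.nan,
          "loss_freq": v["loss"] / n if n else np.nan}
         for a, v in freq.items()]
    ).set_index("arm")
    return calls, arm_freq
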