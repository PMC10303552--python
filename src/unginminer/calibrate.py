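"""Threshold calibration from known positives.

The tuning rule is deliberately simple: for each scalar attribute, take the
minimum-to-maximum envelope over the known inhibitor sequences (optionally
widened by a relative margin), and require the ESI motif under a chosen
leniency mode.  For independent interval filters this envelope is exactly
the tightest configuration that retains every positive, so "retain all
positives with as few false positives as possible" is solved in closed
form — no stochastic search, and the result is reproducible by
construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pandas as pd

from .io import GenomeRecord, ProteinRecord
from .motifs import EsiMode, has_esi_motif
from .pipeline import FilterConfig, passes_all_filters, run_bulk
from .properties import property_vector

__all__ = ["CalibrationError", "CalibrationResult", "calibrate", "leniency_profile"]


class CalibrationError(ValueError):
    """A supplied positive cannot be retained under the requested settings."""


@dataclass
class CalibrationResult:
    """A fitted configuration plus the evidence behind it."""

    config: FilterConfig
    envelope: dict[str, tuple[float, float]]
    retained: dict[str, bool]
    false_positive_count: int | None = None  # None when no background given
    false_positive_ids: list[str] = field(default_factory=list)

    def envelope_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(k, lo, hi) for k, (lo, hi) in self.envelope.items()],
            columns=["attribute", "lo", "hi"],
        )


def _outward(lo: float, hi: float, margin: float) -> tuple[float, float]:
    return lo - margin * abs(lo), hi + margin * abs(hi)


def calibrate(
    positives: Sequence[ProteinRecord],
    background: Sequence[GenomeRecord] = (),
    margin: float = 0.0,
    esi_mode: EsiMode = EsiMode.STRICT_NATURAL,
    base_config: FilterConfig | None = None,
) -> CalibrationResult:
    """Fit the min/max attribute envelope over known positive proteins.

    Every positive must contain the ESI motif under ``esi_mode`` (else
    :class:`CalibrationError` naming the sequence).  With a ``background``
    of genomes, the fitted configuration is applied to them and surviving
    sequences that are not positives are counted as false positives.
    """
    if not positives:
        raise CalibrationError("need at least one positive sequence")
    if margin < 0:
        raise ValueError("margin must be non-negative")
    for rec in positives:
        if not has_esi_motif(rec.seq, esi_mode):
            raise CalibrationError(
                f"positive {rec.id!r} lacks an ESI motif under mode "
                f"{esi_mode.value!r}; calibrate with a more lenient mode or "
                "drop the sequence"
            )
    vectors = {rec.id: property_vector(rec.seq) for rec in positives}

    def env(attr: str) -> tuple[float, float]:
        values = [getattr(v, attr) for v in vectors.values()]
        return _outward(min(values), max(values), margin)

    envelope = {
        "length": env("length"),
        "de_fraction": env("de_fraction"),
        "gravy": env("gravy"),
        "glypro_fraction": env("glypro_fraction"),
        "acid_base_ratio": (
            min(v.acid_base_ratio for v in vectors.values()), math.inf,
        ),
        "mass_da": env("mass_da"),
    }
    ab_min = envelope["acid_base_ratio"][0]
    if math.isfinite(ab_min):
        ab_min -= margin * abs(ab_min)
        envelope["acid_base_ratio"] = (ab_min, math.inf)

    base = base_config or FilterConfig()
    config = replace(
        base,
        min_len=int(math.floor(envelope["length"][0])),
        max_len=int(math.ceil(envelope["length"][1])),
        de_fraction_lo=envelope["de_fraction"][0],
        de_fraction_hi=envelope["de_fraction"][1],
        gravy_lo=envelope["gravy"][0],
        gravy_hi=envelope["gravy"][1],
        glypro_lo=envelope["glypro_fraction"][0],
        glypro_hi=envelope["glypro_fraction"][1],
        acid_base_min=ab_min,
        mass_lo=envelope["mass_da"][0],
        mass_hi=envelope["mass_da"][1],
        esi_mode=esi_mode,
    )

    retained = {rec.id: passes_all_filters(rec.seq, config) for rec in positives}
    if not all(retained.values()):
        missing = [k for k, ok in retained.items() if not ok]
        raise CalibrationError(
            f"internal envelope error: positives {missing} rejected by their own envelope"
        )

    fp_count: int | None = None
    fp_ids: list[str] = []
    if background:
        positive_seqs = {rec.seq for rec in positives}
        bulk = run_bulk(list(background), config)
        for cs in bulk.candidate_sets.values():
            for cand in cs.members:
                if cand.protein.aa_seq not in positive_seqs:
                    fp_ids.append(cand.id)
        fp_count = len(fp_ids)

    return CalibrationResult(
        config=config,
        envelope=envelope,
        retained=retained,
        false_positive_count=fp_count,
        false_positive_ids=fp_ids,
    )


def leniency_profile(
    positives: Sequence[ProteinRecord],
    background: Sequence[GenomeRecord],
    modes: Iterable[EsiMode],
    margin: float = 0.0,
) -> pd.DataFrame:
    """False-positive counts per ESI mode under the calibrated envelope.

    Counts are non-decreasing along the leniency lattice (strict implies
    lenient, natural implies synthetic).
    """
    rows = []
    for mode in modes:
        result = calibrate(positives, background, margin=margin, esi_mode=mode)
        rows.append(
            {"mode": mode.value, "false_positives": result.false_positive_count or 0}
        )
    return pd.DataFrame(rows, columns=["mode", "false_positives"])
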