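"""QEA profiles: fitting, serialisation and compound scoring.

A profile holds one fitted desirability curve per descriptor.  The QEA
score of a molecule is the unweighted geometric mean of its six
desirabilities, computed as exp of the mean log; any non-positive
desirability forces the score to exactly zero.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .binning import continuous_frequencies, integer_frequencies
from .compounds import (
    DESCRIPTOR_CONVENTIONS,
    DESCRIPTOR_NAMES,
    CompoundRecord,
    DescriptorVector,
    compute_descriptors,
    deduplicate,
)
from .desirability import DesirabilityParams, evaluate_desirability, fit_desirability

PROFILE_SCHEMA_VERSION = 1

CONTINUOUS = ("mw", "logp")
DISCRETE = ("hba", "hbd", "nrotb", "narr")

#: Desirabilities above 1 (fit overshoot, tolerated up to 1.05 in the
#: stored model) are clamped to 1 before aggregation.
CLAMP_MAX = 1.0


class ProfileConventionError(RuntimeError):
    """Profile was fitted under different descriptor rule sets."""


class InsufficientDataError(ValueError):
    pass


@dataclass
class QEAProfile:
    """The full fitted algicide-likeness model: six desirability curves."""

    models: dict[str, DesirabilityParams]
    descriptor_conventions: dict[str, str] = field(
        default_factory=lambda: dict(DESCRIPTOR_CONVENTIONS))
    provenance: str = ""

    def __post_init__(self) -> None:
        missing = set(DESCRIPTOR_NAMES) - set(self.models)
        extra = set(self.models) - set(DESCRIPTOR_NAMES)
        if missing or extra:
            raise ValueError(
                f"profile must model exactly {DESCRIPTOR_NAMES}; "
                f"missing={sorted(missing)} extra={sorted(extra)}")

    # ---- serialisation -------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "version": PROFILE_SCHEMA_VERSION,
            "toolkit_version": __version__,
            "descriptor_conventions": self.descriptor_conventions,
            "models": {d: self.models[d].to_dict() for d in DESCRIPTOR_NAMES},
            "provenance": self.provenance,
        }
        return json.dumps(doc, indent=2, sort_keys=True)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")

    @classmethod
    def from_json(cls, text: str) -> "QEAProfile":
        doc = json.loads(text)
        if doc.get("version") != PROFILE_SCHEMA_VERSION:
            raise ValueError(f"unsupported profile version: {doc.get('version')!r}")
        models = {}
        for name, md in doc["models"].items():
            md = dict(md)
            md.pop("descriptor", None)
            models[name] = DesirabilityParams(descriptor=name, **md)
        return cls(models=models,
                   descriptor_conventions=doc.get("descriptor_conventions", {}),
                   provenance=doc.get("provenance", ""))

    @classmethod
    def load(cls, path: str | Path) -> "QEAProfile":
        return cls.from_json(Path(path).read_text(encoding="utf-8"))

    def check_conventions(self) -> None:
        if self.descriptor_conventions != DESCRIPTOR_CONVENTIONS:
            raise ProfileConventionError(
                "profile descriptor conventions do not match this engine: "
                f"profile={self.descriptor_conventions} engine={DESCRIPTOR_CONVENTIONS}")


def aggregate_qea(desirabilities: Sequence[float]) -> float:
    """Combine per-descriptor desirabilities into one [0, 1] QEA score.

    The unweighted geometric mean ``exp((1/n) * sum(ln d_i))`` when every
    desirability is positive; exactly 0 as soon as any is <= 0.
    """
    ds = list(desirabilities)
    if not ds:
        raise ValueError("empty desirability vector")
    if any(d <= 0 for d in ds):
        return 0.0
    return math.exp(sum(math.log(d) for d in ds) / len(ds))


def compound_desirabilities(profile: QEAProfile, desc: DescriptorVector) -> dict[str, float]:
    """Evaluate all six desirability curves at a compound's descriptor values,
    clamped to at most 1."""
    out = {}
    for name in DESCRIPTOR_NAMES:
        d = evaluate_desirability(profile.models[name], getattr(desc, name))
        out[name] = min(float(d), CLAMP_MAX)
    return out


def score_descriptor_vector(profile: QEAProfile, desc: DescriptorVector) -> float:
    return aggregate_qea(list(compound_desirabilities(profile, desc).values()))


def score_compounds(profile: QEAProfile, records: Sequence[CompoundRecord]) -> pd.DataFrame:
    """Score parsed compounds against a fitted profile.

    Returns one row per input record, in input order: the six
    descriptors, the six desirabilities (``d_`` columns) and the QEA
    score.  Invalid records keep their row with a null score and the
    parse failure in ``reason``.
    """
    profile.check_conventions()
    rows = []
    for rec in records:
        row: dict = {"id": rec.id, "smiles": rec.smiles}
        if rec.valid:
            desc = compute_descriptors(rec)
            row.update(desc.as_dict())
            ds = compound_desirabilities(profile, desc)
            row.update({f"d_{k}": v for k, v in ds.items()})
            row["qea"] = aggregate_qea(list(ds.values()))
            row["reason"] = ""
        else:
            row["qea"] = None
            row["reason"] = rec.failure_reason or "invalid"
        rows.append(row)
    cols = (["id", "smiles", *DESCRIPTOR_NAMES,
             *[f"d_{d}" for d in DESCRIPTOR_NAMES], "qea", "reason"])
    return pd.DataFrame(rows).reindex(columns=cols)


def _fit_one(name: str, values: np.ndarray,
             candidate_range: tuple[int, int] | None) -> DesirabilityParams:
    if name in CONTINUOUS:
        freq = continuous_frequencies(values, candidate_range)
    else:
        freq = integer_frequencies(values)
    return fit_desirability(freq, name)


def fit_profile_from_descriptors(
    descriptors: Sequence[DescriptorVector] | pd.DataFrame,
    provenance: str = "",
    candidate_range: tuple[int, int] | None = None,
    min_compounds: int = 30,
) -> QEAProfile:
    """Fit all six desirability curves from pre-computed descriptor values.

    Accepts either a list of :class:`DescriptorVector` or a DataFrame with
    the six descriptor columns (the descriptor-table CSV layout).
    """
    if isinstance(descriptors, pd.DataFrame):
        df = descriptors
    else:
        df = pd.DataFrame([d.as_dict() for d in descriptors])
    df = df.dropna(subset=list(DESCRIPTOR_NAMES))
    n = len(df)
    if n < min_compounds:
        raise InsufficientDataError(
            f"need >= {min_compounds} compounds with descriptors, got {n}")
    models, failures = {}, {}
    for name in DESCRIPTOR_NAMES:
        try:
            models[name] = _fit_one(name, df[name].to_numpy(), candidate_range)
        except Exception as exc:  # collected so the error names every bad fit
            failures[name] = f"{type(exc).__name__}: {exc}"
    if failures:
        raise RuntimeError(f"desirability fit failed for {failures}")
    prov = provenance or f"fitted from {n} compounds"
    return QEAProfile(models=models, provenance=prov)


def fit_profile(
    reference: Sequence[CompoundRecord],
    provenance: str = "",
    candidate_range: tuple[int, int] | None = None,
    min_compounds: int = 30,
) -> QEAProfile:
    """Fit a QEA profile from a reference ("positive") compound set.

    Invalid records are dropped and the set is deduplicated by canonical
    fragment SMILES (first occurrence kept) so repeated literature
    entries do not distort the frequency distributions.
    """
    valid = [r for r in deduplicate(reference) if r.valid]
    if len(valid) < min_compounds:
        raise InsufficientDataError(
            f"need >= {min_compounds} valid deduplicated compounds, got {len(valid)}")
    descs = [compute_descriptors(r) for r in valid]
    prov = provenance or f"fitted from {len(valid)} unique valid compounds"
    return fit_profile_from_descriptors(
        descs, provenance=prov, candidate_range=candidate_range,
        min_compounds=min_compounds)
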