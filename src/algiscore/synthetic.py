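"""Synthetic descriptor distributions and a hand-checkable SMILES panel.

The simulator draws descriptor vectors directly (no chemistry engine in
the loop): continuous descriptors from right-skewed log-normal laws,
discrete descriptors from (optionally shifted) Poisson laws.  The
default "positive" condition emulates a typical algicide reference set
— molecular weights mostly between 200 and 500 g/mol, logP peaking
around 2-5, fewer than five rotatable bonds, one or two aromatic rings,
small hydrogen-bonding counts.  The "decoy" condition is deliberately
diffuse: wider spreads and shifted peaks, standing in for a random
screening-library background.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .compounds import DESCRIPTOR_NAMES, CompoundRecord, DescriptorVector


@dataclass(frozen=True)
class LogNormalLaw:
    """Right-skewed continuous law; median and log-scale shape sigma."""

    median: float
    sigma: float

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.median <= 0 or self.sigma <= 0:
            raise ValueError(f"invalid log-normal parameters {self}")
        return rng.lognormal(mean=np.log(self.median), sigma=self.sigma, size=n)


@dataclass(frozen=True)
class PoissonLaw:
    """Non-negative integer law; optional additive shift (minimum value)."""

    mean: float
    shift: int = 0

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.mean < 0 or self.shift < 0:
            raise ValueError(f"invalid Poisson parameters {self}")
        return rng.poisson(lam=self.mean, size=n) + self.shift


#: Study-condition defaults for a reference ("positive") set.
POSITIVE_LAWS = {
    "mw": LogNormalLaw(median=330.0, sigma=0.30),
    "logp": LogNormalLaw(median=3.0, sigma=0.35),
    "hba": PoissonLaw(mean=3.0),
    "hbd": PoissonLaw(mean=1.2),
    "nrotb": PoissonLaw(mean=3.0),
    "narr": PoissonLaw(mean=0.8, shift=1),
}

#: Diffuse background ("decoy") condition: shifted peaks, wider spread.
DECOY_LAWS = {
    "mw": LogNormalLaw(median=480.0, sigma=0.70),
    "logp": LogNormalLaw(median=1.6, sigma=0.90),
    "hba": PoissonLaw(mean=6.0),
    "hbd": PoissonLaw(mean=3.0),
    "nrotb": PoissonLaw(mean=7.0),
    "narr": PoissonLaw(mean=2.5),
}


@dataclass(frozen=True)
class SimulationSpec:
    """Recipe for one synthetic descriptor set; identical spec + seed
    always reproduce the same draw."""

    n: int
    seed: int
    mode: str = "positive"  # "positive" | "decoy"
    laws: dict | None = None

    def resolved_laws(self) -> dict:
        if self.laws is not None:
            return self.laws
        if self.mode == "positive":
            return POSITIVE_LAWS
        if self.mode == "decoy":
            return DECOY_LAWS
        raise ValueError(f"unknown mode {self.mode!r}")


def simulate_descriptor_set(spec: SimulationSpec) -> list[DescriptorVector]:
    """Draw ``spec.n`` descriptor vectors per the spec's generating laws."""
    if spec.n < 0:
        raise ValueError("n must be >= 0")
    laws = spec.resolved_laws()
    missing = set(DESCRIPTOR_NAMES) - set(laws)
    if missing:
        raise ValueError(f"laws missing descriptors: {sorted(missing)}")
    rng = np.random.default_rng(spec.seed)
    cols = {name: laws[name].sample(rng, spec.n) for name in DESCRIPTOR_NAMES}
    return [
        DescriptorVector(
            mw=float(cols["mw"][i]),
            logp=float(cols["logp"][i]),
            hba=int(cols["hba"][i]),
            hbd=int(cols["hbd"][i]),
            nrotb=int(cols["nrotb"][i]),
            narr=int(cols["narr"][i]),
        )
        for i in range(spec.n)
    ]


def simulate_descriptor_frame(spec: SimulationSpec) -> pd.DataFrame:
    """Same draw as :func:`simulate_descriptor_set`, as a DataFrame whose
    layout matches the descriptor-table CSV accepted by profile fitting."""
    descs = simulate_descriptor_set(spec)
    df = pd.DataFrame([d.as_dict() for d in descs])
    if df.empty:
        df = pd.DataFrame(columns=list(DESCRIPTOR_NAMES))
    df.insert(0, "id", [f"sim{i + 1}" for i in range(len(df))])
    return df


# Small panel of simple molecules whose descriptors are hand-verifiable;
# regression fixture for the descriptor engine.
_SMALL_PANEL = [
    ("benzene", "c1ccccc1"),
    ("toluene", "Cc1ccccc1"),
    ("ethanol", "CCO"),
    ("methanol", "CO"),
    ("propane", "CCC"),
    ("butane", "CCCC"),
    ("cyclohexane", "C1CCCCC1"),
    ("phenol", "Oc1ccccc1"),
    ("aniline", "Nc1ccccc1"),
    ("biphenyl", "c1ccccc1-c1ccccc1"),
    ("naphthalene", "c1ccc2ccccc2c1"),
    ("pyridine", "c1ccncc1"),
    ("acetic_acid", "CC(=O)O"),
    ("acetone", "CC(C)=O"),
    ("diethyl_ether", "CCOCC"),
    ("acetamide", "CC(N)=O"),
    ("n_methylacetamide", "CNC(C)=O"),
    ("styrene", "C=Cc1ccccc1"),
    ("benzoic_acid", "OC(=O)c1ccccc1"),
    ("anisole", "COc1ccccc1"),
]


def fixture_smiles_set(kind: str = "small_panel") -> list[CompoundRecord]:
    """Hard-coded panel of ~20 simple valid SMILES for engine regression tests."""
    if kind != "small_panel":
        raise ValueError(f"unknown fixture kind {kind!r}")
    from .compounds import _make_record

    return [_make_record(name, smi) for name, smi in _SMALL_PANEL]
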