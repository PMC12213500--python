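"""EPA acute aquatic-toxicity categories for EC50/LC50 concentrations.

Five levels from "practically non-toxic" (> 100 mg/L) down to "very
highly toxic" (< 0.1 mg/L).  The decade boundaries use a half-open
convention: each shared boundary belongs to the more toxic category —
exactly 100 mg/L is slightly toxic, 10 mg/L moderately, 1 mg/L highly,
and 0.1 mg/L highly (the "very highly" bin is strictly below 0.1, as
the printed "< 0.1" definition requires).  Toxicity concentrations are
inputs (e.g. predicted EC50/LC50 values supplied as CSV); this module
never predicts them.
"""

from __future__ import annotations

import math
from pathlib import Path

import pandas as pd

#: Severity order, least to most toxic.
CATEGORIES = (
    "practically_nontoxic",
    "slightly",
    "moderately",
    "highly",
    "very_highly",
)

SPECIES = ("T_pyriformis", "D_magna", "P_promelas")
ENDPOINTS = ("EC50", "LC50")


def classify_epa(concentration: float) -> str:
    """EPA five-level category of an acute EC50/LC50 in mg/L.

    > 100 -> practically_nontoxic; (10, 100] -> slightly;
    (1, 10] -> moderately; [0.1, 1] -> highly; < 0.1 -> very_highly.
    """
    if not concentration > 0:
        raise ValueError(f"concentration must be positive (got {concentration})")
    if concentration > 100:
        return "practically_nontoxic"
    if concentration > 10:
        return "slightly"
    if concentration > 1:
        return "moderately"
    if concentration >= 0.1:
        return "highly"
    return "very_highly"


def negative_log_transform(concentration: float) -> float:
    """-log10 of a concentration in mg/L; larger means more toxic."""
    if not concentration > 0:
        raise ValueError(f"concentration must be positive (got {concentration})")
    return -math.log10(concentration)


def annotate_toxicity_table(df: pd.DataFrame) -> pd.DataFrame:
    """Add ``category`` and ``neg_log10`` columns to a toxicity CSV table.

    Expects a ``concentration_mg_L`` column; all other columns
    (compound_id, species, endpoint, duration_h, ...) pass through.
    """
    if "concentration_mg_L" not in df.columns:
        raise ValueError("toxicity table needs a 'concentration_mg_L' column")
    out = df.copy()
    out["category"] = out["concentration_mg_L"].map(classify_epa)
    out["neg_log10"] = out["concentration_mg_L"].map(negative_log_transform)
    return out


def classify_toxicity_csv(in_path: str | Path, out_path: str | Path) -> pd.DataFrame:
    annotated = annotate_toxicity_table(pd.read_csv(in_path))
    annotated.to_csv(out_path, index=False)
    return annotated
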