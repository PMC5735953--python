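"""Library-level orchestration: scan + enrich in one call, and seeded
Monte-Carlo calibration of the full synthetic pipeline.

The calibration helpers answer the two questions one should ask of a
presence/absence enrichment design before trusting it on real promoters:
at the study's sample sizes, how often does the pipeline detect a given
planted-rate difference (power), and how often does it reject when there
is none (type-I error)?
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .enrich import DEFAULT_COMPARISONS, enrichment_report
from .motifs import MotifCatalog, builtin_catalog
from .promoters import PromoterSet
from .scan import build_presence
from .simulate import Planting, StudyDesign, generate_study

__all__ = ["scan_and_enrich", "synthetic_replicate_p", "rejection_rate"]

_SEED_MOD = 2**31


def scan_and_enrich(pset: PromoterSet,
                    catalog: Optional[MotifCatalog] = None,
                    comparisons: Sequence[tuple[str, str]] = tuple(DEFAULT_COMPARISONS),
                    ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Scan a labeled promoter set and report enrichment.

    Returns ``(presence, hits, report)``.
    """
    catalog = catalog or builtin_catalog()
    presence, hits = build_presence(pset, catalog)
    report = enrichment_report(presence, pset.labels, catalog, comparisons)
    return presence, hits, report


def synthetic_replicate_p(design: StudyDesign, motif_name: str,
                          set_a: str = "class_I",
                          set_b: str = "class_II") -> float:
    """Generate one study and return the two-sided enrichment p for one
    motif and one class comparison (only that motif is scanned)."""
    catalog = builtin_catalog()
    pset, _ = generate_study(design, catalog)
    presence, _ = build_presence(pset, catalog.subset([motif_name]))
    report = enrichment_report(presence, pset.labels,
                               catalog.subset([motif_name]),
                               [(set_a, set_b)])
    return float(report["p_two_sided"].iloc[0])


def rejection_rate(motif_name: str, rate_a: float, rate_b: float,
                   n_replicates: int, seed: int,
                   alpha: float = 0.05,
                   base_design: Optional[StudyDesign] = None,
                   set_a: str = "class_I",
                   set_b: str = "class_II") -> tuple[float, np.ndarray]:
    """Fraction of seeded replicates with p < alpha for a planted-rate pair.

    Each replicate regenerates the full study design with ``motif_name``
    planted at ``rate_a`` in ``set_a`` promoters and ``rate_b`` in
    ``set_b`` promoters (no other plantings), then runs scan + enrichment.
    Returns ``(rate, p_values)``.
    """
    base = base_design or StudyDesign()
    p_values = np.empty(n_replicates)
    for r in range(n_replicates):
        design = dataclasses.replace(
            base,
            plantings=(Planting(motif_name, set_a, rate_a),
                       Planting(motif_name, set_b, rate_b)),
            seed=(seed * 100_000 + r) % _SEED_MOD,
        )
        p_values[r] = synthetic_replicate_p(design, motif_name, set_a, set_b)
    return float(np.mean(p_values < alpha)), p_values
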