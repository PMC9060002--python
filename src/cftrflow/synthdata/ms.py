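"""Synthetic AP-MS replicate tables with a known interactome ground truth.

Each condition (wt / F508del) has a true interactor set drawn from a shared
protein universe; the two sets share a common core, emulating interactome
remodelling by the disease mutation. A true interactor appears in each
biological replicate independently with a fixed detection probability,
carrying a passing identification score; decoy rows carry scores at or
below the acceptance threshold (or sub-threshold confidence) and must be
removed by the score filter, never by the replicate-consensus rule alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class MsSimParams:
    n_replicates: int = 3
    universe_size: int = 3000
    n_true: dict[str, int] = field(default_factory=lambda: {"wt": 234, "f508del": 352})
    core_size: int = 214
    detection_probability: float = 0.9
    decoy_rate: float = 0.05  # fraction of the universe appearing as decoy rows per replicate
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.detection_probability <= 1.0:
            raise ValueError("detection probability must be in (0, 1]")
        if self.core_size > min(self.n_true.values()):
            raise ValueError("common core larger than a condition's true set")
        if sum(self.n_true.values()) - self.core_size > self.universe_size:
            raise ValueError("universe too small for the requested true sets")


def generate_ms_replicates(
    params: MsSimParams,
) -> tuple[dict[str, list[pd.DataFrame]], dict[str, frozenset[str]]]:
    """Per-condition replicate tables and the true interactor sets.

    Returns ``(tables, truth)`` where ``tables[cond]`` is a list of
    ``n_replicates`` DataFrames with columns accession, gene, unused_score,
    confidence, and ``truth[cond]`` the planted accession set.
    """
    rng = np.random.default_rng(params.seed)
    universe = np.array([f"P{i:05d}" for i in range(params.universe_size)])
    gene_of = {acc: f"GENE{i}" for i, acc in enumerate(universe)}

    order = rng.permutation(params.universe_size)
    core = universe[order[: params.core_size]]
    cursor = params.core_size
    truth: dict[str, frozenset[str]] = {}
    for cond, n in params.n_true.items():
        extra = universe[order[cursor : cursor + (n - params.core_size)]]
        cursor += n - params.core_size
        truth[cond] = frozenset(core) | frozenset(extra)

    tables: dict[str, list[pd.DataFrame]] = {}
    n_decoys = int(round(params.decoy_rate * params.universe_size))
    for cond, true_set in truth.items():
        true_arr = np.array(sorted(true_set))
        reps = []
        for _ in range(params.n_replicates):
            detected = true_arr[rng.random(true_arr.size) < params.detection_probability]
            rows = [
                {
                    "accession": acc,
                    "gene": gene_of[acc],
                    "unused_score": float(rng.uniform(1.4, 30.0)),
                    "confidence": float(rng.uniform(95.0, 100.0)),
                }
                for acc in detected
            ]
            decoys = rng.choice(universe, size=n_decoys, replace=False)
            for acc in decoys:
                if rng.random() < 0.5:  # sub-threshold score
                    score, conf = float(rng.uniform(0.0, 1.3)), float(rng.uniform(95.0, 100.0))
                else:  # sub-threshold confidence
                    score, conf = float(rng.uniform(1.4, 30.0)), float(rng.uniform(0.0, 94.9))
                rows.append(
                    {
                        "accession": acc,
                        "gene": gene_of[acc],
                        "unused_score": score,
                        "confidence": conf,
                    }
                )
            reps.append(pd.DataFrame(rows, columns=["accession", "gene", "unused_score", "confidence"]))
        tables[cond] = reps
    return tables, truth
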