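"""Candidate scanning of a target mRNA.

Enumerates every 19-mer target-site window, predicts its knockdown
efficacy with a trained model, keeps windows above an efficacy threshold,
and partitions survivors by whole-duplex stacking energy: candidates with
whole_dG >= -34.6 kcal/mol form the high-confidence set (recommended for
selection), the rest the low-confidence set.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .evaluation import DG_THRESHOLD
from .io import enumerate_candidates
from .thermo import ThermoParams, whole_dG

HIGH_CONFIDENCE = "high_confidence"
LOW_CONFIDENCE = "low_confidence"


def scan_mrna(
    model,
    mrna_seq: str,
    parent_id: str = "mrna",
    efficacy_threshold: float = 70.0,
    dG_threshold: float = DG_THRESHOLD,
    params: ThermoParams | None = None,
) -> pd.DataFrame:
    """Scan an mRNA and return the surviving candidates as a table.

    Columns: id, start, sequence, predicted_efficacy, whole_dG,
    partition.  Sorted by partition (high-confidence first), then
    predicted efficacy descending, then start position ascending.
    """
    candidates = enumerate_candidates(mrna_seq, parent_id=parent_id)
    seqs = [c.sense_seq for c in candidates]
    pred = np.asarray(model.predict(seqs), float)
    dg = np.array([whole_dG(s, params) for s in seqs])
    starts = [int(c.id.rsplit(":", 1)[1].split("-")[0]) for c in candidates]
    df = pd.DataFrame(
        {
            "id": [c.id for c in candidates],
            "start": starts,
            "sequence": seqs,
            "predicted_efficacy": pred,
            "whole_dG": dg,
        }
    )
    df["partition"] = np.where(df.whole_dG >= dG_threshold, HIGH_CONFIDENCE, LOW_CONFIDENCE)
    df = df[df.predicted_efficacy >= efficacy_threshold]
    df = df.sort_values(
        by=["partition", "predicted_efficacy", "start"],
        ascending=[True, False, True],  # high_confidence sorts before low_
    ).reset_index(drop=True)
    return df


def format_scan_report(
    df: pd.DataFrame,
    parent_id: str,
    efficacy_threshold: float,
    dG_threshold: float,
) -> str:
    """Three-part text report: all survivors, then each dG partition."""
    lines = [
        f"# candidate siRNA scan of {parent_id}",
        f"# efficacy threshold: {efficacy_threshold}%  |  "
        f"whole-dG threshold: {dG_threshold} kcal/mol",
        f"# recommended: the dG >= {dG_threshold} (high-confidence) set",
        "",
    ]
    if df.empty:
        lines.append("no candidate siRNAs passed the efficacy threshold")
        return "\n".join(lines) + "\n"

    def block(title: str, sub: pd.DataFrame) -> None:
        lines.append(f"== {title} ({len(sub)} candidates) ==")
        lines.append("id\tsequence\tpredicted_efficacy\twhole_dG")
        for row in sub.itertuples(index=False):
            lines.append(
                f"{row.id}\t{row.sequence}\t{row.predicted_efficacy:.2f}\t"
                f"{row.whole_dG:.2f}"
            )
        lines.append("")

    block("all candidates above threshold", df)
    block(
        f"dG >= {dG_threshold} kcal/mol (high confidence)",
        df[df.partition == HIGH_CONFIDENCE],
    )
    block(
        f"dG < {dG_threshold} kcal/mol (low confidence)",
        df[df.partition == LOW_CONFIDENCE],
    )
    return "\n".join(lines)
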