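"""Reading event tables and writing model/segmentation/report artifacts.

Event tables are delimited text (CSV or TSV, inferred from the extension)
with a ``sequence_id`` column followed by feature columns; alternatively a
table may carry K density columns (``density`` mode) or a single integer
``label`` column (``labels`` mode).  All coordinates in outputs are 0-based
half-open intervals.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from .compare import MotifComparison
from .emissions import EventSequence, SymbolProbSequence, hard_label_rho
from .engine import Dictionary
from .pattern import format_motif
from .segment import Segmentation


def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def read_sequences(
    path: str | Path, mode: str = "features", K: int | None = None
) -> List[EventSequence] | List[SymbolProbSequence]:
    """Read an event table grouped by ``sequence_id`` preserving row order.

    ``mode`` is one of ``features`` (numeric feature columns), ``densities``
    (K nonnegative density columns) or ``labels`` (one integer ``label``
    column, converted to near-one-hot density rows; requires ``K``).
    """
    df = pd.read_csv(path, sep=_sep_for(path))
    if "sequence_id" not in df.columns:
        raise ValueError(f"{path}: missing required column 'sequence_id'")
    value_cols = [c for c in df.columns if c != "sequence_id"]
    if not value_cols:
        raise ValueError(f"{path}: no data columns")
    if df[value_cols].isna().any().any():
        row = int(df[value_cols].isna().any(axis=1).idxmax()) + 2  # header + 1-base
        raise ValueError(f"{path}: missing/ragged value at line {row}")

    out = []
    for sid, group in df.groupby("sequence_id", sort=False):
        vals = group[value_cols].to_numpy()
        if mode == "features":
            out.append(EventSequence(sequence_id=str(sid), features=vals.astype(float)))
        elif mode == "densities":
            neg = np.argwhere(vals < 0)
            if neg.size:
                row = int(group.index[neg[0][0]]) + 2
                raise ValueError(f"{path}: negative density at line {row}")
            out.append(SymbolProbSequence(sequence_id=str(sid), rho=vals.astype(float)))
        elif mode == "labels":
            if K is None:
                raise ValueError("labels mode requires the alphabet size K")
            labels = vals[:, 0].astype(int)
            out.append(
                SymbolProbSequence(sequence_id=str(sid), rho=hard_label_rho(labels, K))
            )
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return out


def write_event_table(
    path: str | Path, sequences: Sequence[EventSequence]
) -> None:
    frames = []
    for seq in sequences:
        df = pd.DataFrame(
            seq.features, columns=[f"f{j}" for j in range(seq.features.shape[1])]
        )
        df.insert(0, "sequence_id", seq.sequence_id)
        frames.append(df)
    pd.concat(frames).to_csv(path, sep=_sep_for(path), index=False)


def write_dictionary(path: str | Path, dic: Dictionary, **metadata) -> None:
    Path(path).write_text(json.dumps(dic.to_json(**metadata), indent=1))


def read_dictionary(path: str | Path) -> Dictionary:
    return Dictionary.from_json(json.loads(Path(path).read_text()))


def write_segmentations(
    path: str | Path,
    segmentations: Dict[str, Segmentation],
    glyphs: Sequence[str] | None = None,
) -> None:
    """Segmentations as TSV: sequence_id, start, end (0-based half-open),
    motif, log-likelihood contribution."""
    rows = []
    for sid, seg in segmentations.items():
        for s in seg.segments:
            rows.append(
                {
                    "sequence_id": sid,
                    "start": s.start,
                    "end": s.end,
                    "motif": format_motif(s.motif, glyphs),
                    "log_likelihood": s.log_likelihood,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_comparison(
    path: str | Path,
    comparisons: Sequence[MotifComparison],
    glyphs: Sequence[str] | None = None,
) -> None:
    rows = [
        {
            "motif": format_motif(c.motif, glyphs),
            "neg_log10_p": c.neg_log10_p,
            "counts_A": c.counts_A,
            "counts_B": c.counts_B,
            "flagged": c.flagged,
            "pct_individuals": c.pct_individuals,
            "coverage": c.coverage,
        }
        for c in comparisons
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
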