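"""File IO: participant tables, trial-level sessions, and norm artifacts.

CSV dialect is UTF-8 with a header row and comma separators.  Sex is
encoded ``F``/``M`` in files and mapped to a 0/1 indicator (``F`` = 0,
``M`` = 1) when used as a regression predictor.  Norm artifacts
(correction equations, cutpoint sets) serialize to JSON or YAML and
round-trip losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import pandas as pd
import yaml

from .cutpoints import CutpointSet
from .errors import ValidationError
from .norming import CorrectionEquation
from .session import (
    SpanBlock,
    SpanSession,
    SupraspanSession,
    SupraspanTrial,
    TrialScoreTable,
    parse_sequence,
)

__all__ = [
    "read_participants",
    "write_participants",
    "read_trial_sessions",
    "write_equation",
    "read_equation",
    "write_cutpoints",
    "read_cutpoints",
    "load_score_table",
    "load_span_protocol",
]

PARTICIPANT_COLUMNS = ("participant_id", "age", "education", "sex", "cs_raw", "cssl_raw", "cssr_raw")
_NUMERIC = ("age", "education", "cs_raw", "cssl_raw", "cssr_raw")


def read_participants(path) -> pd.DataFrame:
    """Read and validate a participant table CSV.

    Requires participant_id, age, education, sex, cs_raw, cssl_raw and
    cssr_raw; numeric columns must parse and be non-missing; sex must be F
    or M.  A ``sex_indicator`` column (F=0, M=1) is added for use as a
    regression predictor.
    """
    df = pd.read_csv(path)
    missing = [c for c in PARTICIPANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    problems = []
    for col in _NUMERIC:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna()].tolist()
        if bad:
            problems.append(f"column {col!r}: non-numeric or blank in rows {bad[:10]}")
        df[col] = vals
    sex = df["sex"].astype(str).str.strip().str.upper()
    bad_sex = df.index[~sex.isin(["F", "M"])].tolist()
    if bad_sex:
        problems.append(f"column 'sex': values outside F/M in rows {bad_sex[:10]}")
    if problems:
        raise ValidationError(f"{path}: " + "; ".join(problems))
    df["sex"] = sex
    df["sex_indicator"] = (sex == "M").astype(int)
    return df


def write_participants(df: pd.DataFrame, path) -> None:
    df.loc[:, [c for c in PARTICIPANT_COLUMNS if c in df.columns]].to_csv(path, index=False)


def read_trial_sessions(path, score_table: TrialScoreTable | None = None) -> dict:
    """Read a long-format trial-level CSV into per-participant sessions.

    One row per trial with columns ``participant_id, test, block_length or
    trial_index, target, response`` (sequences dash-separated).  Returns
    ``{participant_id: {"cs": SpanSession, "cssl": SupraspanSession}}``;
    the CSSR recall row (test ``CSSR``) is attached to the supraspan
    session.
    """
    df = pd.read_csv(path)
    required = {"participant_id", "test", "target", "response"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    sessions: dict = {}
    for pid, group in df.groupby("participant_id", sort=False):
        entry: dict = {}
        cs_rows = group[group["test"].str.upper() == "CS"]
        if not cs_rows.empty:
            if "block_length" not in cs_rows.columns or cs_rows["block_length"].isna().any():
                raise ValidationError(f"{path}: CS rows for {pid} need block_length")
            blocks = []
            for length, brows in cs_rows.groupby("block_length", sort=True):
                targets = [parse_sequence(t) for t in brows["target"]]
                responses = [
                    parse_sequence(r) for r in brows["response"] if str(r) not in ("", "nan")
                ]
                blocks.append(SpanBlock(length=int(length), targets=targets, responses=responses))
            entry["cs"] = SpanSession(blocks=blocks)
        cssl_rows = group[group["test"].str.upper() == "CSSL"]
        recall_rows = group[group["test"].str.upper() == "CSSR"]
        if not cssl_rows.empty:
            if "trial_index" in cssl_rows.columns:
                cssl_rows = cssl_rows.sort_values("trial_index")
            target = parse_sequence(cssl_rows["target"].iloc[0])
            trials = [SupraspanTrial(parse_sequence(r)) for r in cssl_rows["response"]]
            recall = None
            if not recall_rows.empty:
                recall = SupraspanTrial(parse_sequence(recall_rows["response"].iloc[0]))
            entry["cssl"] = SupraspanSession(trials=trials, target=target, recall=recall)
        sessions[pid] = entry
    return sessions


# ---------------------------------------------------------------------------
# Norm artifacts
# ---------------------------------------------------------------------------

def _dump(obj: dict, path: Union[str, Path]) -> None:
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(obj, sort_keys=False))
    else:
        path.write_text(json.dumps(obj, indent=2))


def _load(path: Union[str, Path]) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def write_equation(equation: CorrectionEquation, path) -> None:
    _dump(equation.to_dict(), path)


def read_equation(path) -> CorrectionEquation:
    return CorrectionEquation.from_dict(_load(path))


def write_cutpoints(cutpoints: CutpointSet, path) -> None:
    d = cutpoints.to_dict()
    d["percentiles"] = {repr(k): v for k, v in d["percentiles"].items()}
    _dump(d, path)


def read_cutpoints(path) -> CutpointSet:
    d = _load(path)
    d["percentiles"] = {float(k): v for k, v in d["percentiles"].items()}
    return CutpointSet.from_dict(d)


def load_score_table(path) -> TrialScoreTable:
    """Load a supraspan partial-credit score table from YAML/JSON config."""
    data = _load(path)
    scores = data.get("scores", data)
    return TrialScoreTable(scores={str(k): float(v) for k, v in scores.items()})


def load_span_protocol(path) -> list:
    """Load CS target sequences: a list of blocks ``{length, targets: [...]}.``"""
    data = _load(path)
    blocks = []
    for entry in data["blocks"]:
        targets = [parse_sequence(t) for t in entry["targets"]]
        blocks.append({"length": int(entry["length"]), "targets": targets})
    lengths = [b["length"] for b in blocks]
    if any(b <= a for a, b in zip(lengths, lengths[1:])):
        raise ValidationError(f"protocol block lengths {lengths} not strictly increasing")
    return blocks


def default_span_protocol_path() -> Path:
    return Path(__file__).parent / "config" / "span_protocol.yaml"


def default_score_table_path() -> Path:
    return Path(__file__).parent / "config" / "trial_scores.yaml"
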