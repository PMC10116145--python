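"""Readers, writers and report rendering.

Cohort and pair tables travel as comma-separated text with a header row;
session records, generator specs, coefficient sets and reports are JSON.
Sex is accepted as M/F or 1/0 and race as AA/nonAA or 1/0 and normalized
to indicators on read.  Every report embeds the tool version, the
coefficient-set identifier and the seed so a run can be reproduced.
"""

from __future__ import annotations

import json
from typing import Any, Mapping

import pandas as pd

from . import __version__
from .battery import (
    PSTKey,
    PSTResponseStream,
    SymbolID,
    VMTStimulus,
    VMTTrialResponse,
)

SCHEMA_VERSION = 1

_SEX_CODES = {"m": 1, "male": 1, "1": 1, "f": 0, "female": 0, "0": 0}
_RACE_CODES = {"aa": 1, "1": 1, "nonaa": 0, "non-aa": 0, "0": 0}


class MalformedInputError(ValueError):
    """An input row cannot be parsed; the message carries the line number."""


def _normalize_code(value, codes: Mapping[str, int], column: str, line: int) -> int:
    key = str(value).strip().lower()
    if key not in codes:
        raise MalformedInputError(f"line {line}: cannot parse {column}={value!r}")
    return codes[key]


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort table (CSV) and normalize sex/race codings.

    Expected columns include ``age, education, sex, race``; empty fields
    become missing values.  Unknown codings raise with the line number.
    """
    df = pd.read_csv(path)
    for col, codes in (("sex", _SEX_CODES), ("race", _RACE_CODES)):
        if col in df.columns:
            df[col] = [
                _normalize_code(v, codes, col, i + 2) if pd.notna(v) else v
                for i, v in enumerate(df[col])
            ]
    return df


def write_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_pairs(path) -> pd.DataFrame:
    """Read a paired-measurements table (columns id, t1, t2)."""
    df = pd.read_csv(path)
    for col in ("t1", "t2"):
        if col not in df.columns:
            raise MalformedInputError(f"pairs table missing column {col!r}")
    return df


# ---------------------------------------------------------------------------
# Session records (JSON)


def _symbol_to_json(sym: SymbolID) -> dict:
    return {"category": sym.category, "exemplar_index": sym.exemplar_index}


def _symbol_from_json(d: Mapping) -> SymbolID:
    return SymbolID(category=d["category"], exemplar_index=d["exemplar_index"])


def _placements_to_json(placements: Mapping[tuple[int, int], SymbolID]) -> list[dict]:
    # cells serialized as 1-based [row, col]
    return [
        {"cell": list(cell), **_symbol_to_json(sym)}
        for cell, sym in sorted(placements.items())
    ]


def _placements_from_json(entries) -> dict[tuple[int, int], SymbolID]:
    return {tuple(e["cell"]): _symbol_from_json(e) for e in entries}


def vmt_session_to_json(
    stimuli: list[VMTStimulus], responses: list[VMTTrialResponse]
) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "test": "VMT",
        "trials": [
            {
                "stimulus": {
                    "pattern_id": stim.pattern_id,
                    "assignment": _placements_to_json(stim.assignment),
                },
                "response": _placements_to_json(resp.placements),
            }
            for stim, resp in zip(stimuli, responses)
        ],
    }


def vmt_session_from_json(doc: Mapping) -> tuple[list[VMTStimulus], list[VMTTrialResponse]]:
    stimuli, responses = [], []
    for trial in doc["trials"]:
        stimuli.append(
            VMTStimulus(
                pattern_id=trial["stimulus"]["pattern_id"],
                assignment=_placements_from_json(trial["stimulus"]["assignment"]),
            )
        )
        responses.append(VMTTrialResponse(placements=_placements_from_json(trial["response"])))
    return stimuli, responses


def pst_session_to_json(key: PSTKey, stream: PSTResponseStream, duration_s: float = 120.0) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "test": "PST",
        "key": [{"symbol": s, "digit": d} for s, d in key.pairs.items()],
        "items": list(stream.items),
        "presses": [[t, d] for t, d in stream.presses],
        "duration_s": duration_s,
    }


def pst_session_from_json(doc: Mapping) -> tuple[PSTKey, PSTResponseStream, float]:
    key = PSTKey(pairs={e["symbol"]: e["digit"] for e in doc["key"]})
    stream = PSTResponseStream(
        items=tuple(doc["items"]),
        presses=tuple((float(t), int(d)) for t, d in doc["presses"]),
    )
    return key, stream, float(doc.get("duration_s", 120.0))


def load_session(path) -> Mapping:
    with open(path) as fh:
        return json.load(fh)


def save_json(doc: Mapping, path) -> None:
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")


def make_report(
    kind: str,
    payload: Mapping[str, Any],
    coefficient_set_id: str | None = None,
    seed: int | None = None,
) -> dict:
    """Wrap results in a provenance-carrying report document."""
    return {
        "schema_version": SCHEMA_VERSION,
        "tool": "c3b",
        "version": __version__,
        "kind": kind,
        "coefficient_set_id": coefficient_set_id,
        "seed": seed,
        "results": dict(payload),
    }
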