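"""File formats, manifests, and the regressor-table export.

One TSV dialect throughout: tab-separated, UTF-8, '.' decimal, 'NA' for
missing values. Behavioral records round-trip exactly, including missed-trial
flags. Nested results (fits, reports) are JSON.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import RECORD_COLUMNS, TIMING_COLUMNS, BehavioralRecord

NA = "NA"

_BOOL_COLUMNS = ("reward_available", "missed")
_INT_COLUMNS = ("run", "block", "trial", "quartet", "category", "reward")


class RecordParseError(ValueError):
    pass


def write_record(record: BehavioralRecord, path) -> None:
    df = record.trials.copy()
    df.loc[df["missed"], "chosen_action"] = pd.NA
    df.loc[df["missed"], "reaction_time"] = pd.NA
    df.to_csv(path, sep="\t", index=False, na_rep=NA)


def read_record(path) -> BehavioralRecord:
    df = pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise RecordParseError(f"{path}: missing mandatory columns {missing}")
    for col in _BOOL_COLUMNS:
        if df[col].dtype != bool:
            df[col] = df[col].map({"True": True, "False": False,
                                   True: True, False: False})
            if df[col].isna().any():
                row = int(df.index[df[col].isna()][0])
                raise RecordParseError(
                    f"{path}: non-boolean value in column {col!r}, row {row}")
            df[col] = df[col].astype(bool)
    for col in _INT_COLUMNS:
        try:
            df[col] = df[col].astype(int)
        except (TypeError, ValueError) as e:
            raise RecordParseError(f"{path}: column {col!r}: {e}") from None
    if (df["trial"].to_numpy() != np.arange(1, len(df) + 1)).any():
        raise RecordParseError(f"{path}: trial numbering is not contiguous")
    resp = ~df["missed"]
    if df.loc[resp, "chosen_action"].isna().any():
        row = int(df.index[resp & df["chosen_action"].isna()][0])
        raise RecordParseError(
            f"{path}: non-missed trial without chosen_action at row {row}")
    df.loc[df["missed"], "chosen_action"] = None
    return BehavioralRecord(trials=df)


def export_regressor_table(record: BehavioralRecord,
                           traces: pd.DataFrame | None = None) -> pd.DataFrame:
    """Event table for downstream GLM use: one cue, one ISI and one outcome
    row per trial, with the latent value and prediction-error traces as
    parametric modulators. Value signals persist beyond stimulus offset
    through the ISI, so the cue-locked modulators (V, chosen Q, SVPE) are
    carried on both the cue and ISI rows; the AVPE rides the outcome row.
    Missed trials emit error-feedback rows without an AVPE.
    """
    traces = traces if traces is not None else record.traces
    if traces is None:
        raise ValueError("record has no latent traces; simulate with "
                         "record_traces=True or replay under fitted "
                         "parameters first")
    tr = record.trials.reset_index(drop=True)
    for col in TIMING_COLUMNS:
        if col not in tr.columns:
            raise ValueError(f"record lacks timing column {col!r}")
    chosen_right = (tr["chosen_action"] == "right").to_numpy()
    q_chosen = np.where(chosen_right, traces["value_right"],
                        traces["value_left"])
    q_chosen = np.where(tr["missed"], np.nan, q_chosen)
    rows = []
    for i, row in tr.iterrows():
        base = {"trial": row["trial"], "run": row["run"],
                "missed": bool(row["missed"]),
                "V0": traces.loc[i, "V0"], "q_chosen": q_chosen[i],
                "svpe": traces.loc[i, "svpe"],
                "reaction_time": row["reaction_time"]}
        rows.append({**base, "event": "cue", "onset": row["cue_onset"],
                     "duration": row["isi_onset"] - row["cue_onset"],
                     "avpe": np.nan})
        rows.append({**base, "event": "isi", "onset": row["isi_onset"],
                     "duration": row["outcome_onset"] - row["isi_onset"],
                     "avpe": np.nan})
        rows.append({**base,
                     "event": "error_feedback" if row["missed"] else "outcome",
                     "onset": row["outcome_onset"], "duration": 1.0,
                     "avpe": np.nan if row["missed"]
                     else traces.loc[i, "avpe"]})
    cols = ["trial", "run", "event", "onset", "duration", "missed",
            "V0", "q_chosen", "svpe", "avpe", "reaction_time"]
    return pd.DataFrame(rows)[cols]


# ---------------------------------------------------------------------------
# run manifest
# ---------------------------------------------------------------------------

def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Snapshot of a pipeline stage: config, seeds and output checksums.

    Re-running a stage with the recorded seeds must reproduce every output
    byte-identically (verified by :meth:`verify`).
    """
    stage: str
    seed: int
    config: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)  # path -> sha256

    def add_output(self, path) -> None:
        self.outputs[str(path)] = file_checksum(path)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1, default=str)

    @classmethod
    def read(cls, path) -> "RunManifest":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)

    def verify(self) -> dict[str, bool]:
        return {p: file_checksum(p) == h for p, h in self.outputs.items()}
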