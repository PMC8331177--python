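"""Readers, writers and the one-command reproduction pipeline.

The pipeline stages share two long-format CSV schemas:

* choices.csv — one row per administered trial: ``participant_id,
  group, condition, magnitude, delayed_amount, delay_months, trial,
  immediate_offer, choice``;
* auc.csv — one row per participant x condition x magnitude cell:
  ``participant_id, group, condition, magnitude, auc, k, r_squared,
  n_inconsistent``.

``reproduce`` runs the full group-level analysis on an AuC table (and,
when trial-level data are available, on the inconsistency counts) and
packages every statistic with provenance into a single JSON-serializable
bundle.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import curves as cv
from . import inference as inf
from . import staircase as sc

__all__ = [
    "ParseError",
    "ResultsBundle",
    "analyze_svs",
    "choices_to_svs",
    "effect_summaries",
    "read_auc_source",
    "read_choices",
    "reproduce",
    "write_choices",
]

log = logging.getLogger("ddcurve")

CHOICE_COLUMNS = [
    "participant_id",
    "group",
    "condition",
    "magnitude",
    "delayed_amount",
    "delay_months",
    "trial",
    "immediate_offer",
    "choice",
]

AUC_COLUMNS = ["participant_id", "group", "condition", "magnitude", "auc"]

_BLOCK_KEYS = ["participant_id", "group", "condition", "magnitude",
               "delayed_amount", "delay_months"]


class ParseError(ValueError):
    """A table failed validation; the message names the offending row."""


def read_choices(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format choice table.

    Lines starting with ``#`` (provenance headers written by the
    simulator) are ignored.  Unknown columns are preserved.
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in CHOICE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"missing required column(s): {missing}")
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if row.choice not in ("immediate", "delayed"):
            raise ParseError(f"row {i}: unknown choice label {row.choice!r}")
        if row.condition not in sc.CONDITIONS:
            raise ParseError(f"row {i}: unknown condition label {row.condition!r}")
    offers = pd.to_numeric(df["immediate_offer"], errors="coerce")
    bad = offers.isna() | (offers != offers.round())
    if bad.any():
        raise ParseError(
            f"row {int(bad.idxmax()) + 2}: immediate_offer is not an integer"
        )
    amounts = pd.to_numeric(df["delayed_amount"], errors="coerce")
    out_of_range = (offers < 0) | (offers > amounts)
    if out_of_range.any():
        raise ParseError(
            f"row {int(out_of_range.idxmax()) + 2}: offer outside [0, delayed_amount]"
        )
    df["immediate_offer"] = offers.astype(int)
    log.info("read_choices: %d rows from %s", len(df), path)
    return df


def write_choices(df: pd.DataFrame, path: str | Path,
                  header_comments: Mapping[str, object] | None = None) -> None:
    """Write a choice table, optionally with ``# key: value`` provenance lines."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for key, val in (header_comments or {}).items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, index=False)


def choices_to_svs(choices: pd.DataFrame) -> pd.DataFrame:
    """Replay every staircase block, validating stored offers.

    Returns one row per participant x condition x magnitude x delay with
    the normalized subjective value.
    """
    rows = []
    for keys, block in choices.groupby(_BLOCK_KEYS, sort=True):
        recs = [
            sc.ChoiceRecord(
                participant_id=str(keys[0]),
                group=str(keys[1]),
                condition=str(keys[2]),
                magnitude=str(keys[3]),
                delayed_amount=int(keys[4]),
                delay_months=float(keys[5]),
                trial=int(r.trial),
                immediate_offer=int(r.immediate_offer),
                choice=r.choice,
            )
            for r in block.itertuples(index=False)
        ]
        sv = sc.replay_block(recs)
        rows.append(dict(zip(_BLOCK_KEYS, keys)) | {"sv": sv})
    out = pd.DataFrame(rows)
    log.info("choices_to_svs: %d blocks replayed", len(out))
    return out


def analyze_svs(svs: pd.DataFrame) -> pd.DataFrame:
    """Per-cell discounting measures from a subjective-value table.

    For each participant x condition x magnitude: the AuC, the
    hyperbolic per-day discount rate k with its R², and the number of
    inconsistent preferences.
    """
    rows = []
    keys = ["participant_id", "group", "condition", "magnitude"]
    for key_vals, cell in svs.groupby(keys, sort=True):
        cell = cell.sort_values("delay_months")
        curve = cv.DiscountingCurve(
            participant_id=str(key_vals[0]),
            condition=str(key_vals[2]),
            magnitude=str(key_vals[3]),
            delayed_amount=int(cell["delayed_amount"].iloc[0]),
            delays_months=tuple(cell["delay_months"]),
            svs=tuple(cell["sv"]),
        )
        fit = cv.fit_hyperbolic(curve)
        rows.append(
            dict(zip(keys, key_vals))
            | {
                "auc": cv.auc(curve).auc,
                "k": fit.k,
                "r_squared": fit.r_squared,
                "n_inconsistent": cv.count_inconsistencies(curve),
            }
        )
    return pd.DataFrame(rows)


def read_auc_source(path: str | Path,
                    column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a per-participant AuC table, mapping columns via config.

    ``column_map`` maps the canonical names (participant_id, group,
    condition, magnitude, auc) to the names used in the file — deposited
    source-data exports vary in layout, so the reader is configuration
    driven rather than hard-coded.
    """
    df = pd.read_csv(path, comment="#")
    column_map = dict(column_map or {})
    rename = {v: k for k, v in column_map.items()}
    df = df.rename(columns=rename)
    missing = [c for c in AUC_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(
            f"unmapped column(s) {missing}; available: {sorted(df.columns)}"
        )
    return df[[c for c in df.columns if c in set(AUC_COLUMNS) | set(df.columns)]]


def effect_summaries(auc_table: pd.DataFrame) -> dict:
    """Per-group summaries of the EFT and magnitude effects.

    EFT effect: participant's mean AuC in the EFT condition minus the
    Standard condition, collapsed over magnitudes.  Magnitude effect:
    large minus small, collapsed over conditions.
    """
    wide = auc_table.pivot_table(
        index=["participant_id", "group"], columns=["condition", "magnitude"],
        values="auc",
    )
    eft = wide["EFT"].mean(axis=1) - wide["Standard"].mean(axis=1)
    mag = (
        wide.xs("large", axis=1, level="magnitude").mean(axis=1)
        - wide.xs("small", axis=1, level="magnitude").mean(axis=1)
    )
    out = {}
    for name, series in (("eft_effect", eft), ("magnitude_effect", mag)):
        out[name] = {}
        for group, vals in series.groupby(level="group"):
            out[name][group] = inf.GroupSummary(
                n=len(vals), mean=float(vals.mean()), sd=float(vals.std(ddof=1))
            )
    return out


@dataclass
class ResultsBundle:
    """Every group-level result of one pipeline run, with provenance."""

    auc_anova: pd.DataFrame
    post_hoc: dict
    effect_summaries: dict
    bayes: dict
    inconsistency_anova: pd.DataFrame | None = None
    inconsistency_post_hoc: dict | None = None
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def conv(obj):
            if isinstance(obj, pd.DataFrame):
                return obj.to_dict(orient="records")
            if isinstance(obj, inf.GroupSummary):
                return {"n": obj.n, "mean": obj.mean, "sd": obj.sd}
            if isinstance(obj, inf.BayesResult):
                return {"bf10": obj.bf10, "prior_scale": obj.prior_scale}
            if isinstance(obj, (inf.LsdResult, inf.TTestResult)):
                return obj._asdict()
            if isinstance(obj, dict):
                return {str(k): conv(v) for k, v in obj.items()}
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj

        return {
            "auc_anova": conv(self.auc_anova),
            "post_hoc": conv(self.post_hoc),
            "effect_summaries": conv(self.effect_summaries),
            "bayes": conv(self.bayes),
            "inconsistency_anova": conv(self.inconsistency_anova),
            "inconsistency_post_hoc": conv(self.inconsistency_post_hoc),
            "provenance": conv(self.provenance),
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text


def _table_checksum(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        df.to_csv(index=False).encode("utf-8")
    ).hexdigest()


def reproduce(
    auc_table: pd.DataFrame,
    trial_table: pd.DataFrame | None = None,
    exclude_ids: Sequence[str] | None = None,
    prior_scale: float = inf.DEFAULT_PRIOR_SCALE,
    provenance: Mapping[str, object] | None = None,
) -> ResultsBundle:
    """Run the full group-level analysis stack on an AuC table.

    Three-way mixed ANOVA (group x condition x magnitude) on AuC with
    Fisher LSD post hocs on the group-by-magnitude cells, per-group EFT
    and magnitude effect summaries with their JZS Bayes factors, and —
    when a trial-level or per-cell inconsistency table is supplied — the
    matching ANOVA on inconsistent-preference counts.  ``exclude_ids``
    supports sensitivity re-analyses that drop named participants.
    """
    auc_table = auc_table.copy()
    if exclude_ids:
        auc_table = auc_table[~auc_table["participant_id"].isin(exclude_ids)]
    checksum = _table_checksum(auc_table)

    anova = inf.mixed_anova(
        auc_table, dv="auc", between="group", within=["condition", "magnitude"]
    )
    lsd = lambda a, b: inf.fisher_lsd(  # noqa: E731
        auc_table, "auc", "group", ["condition", "magnitude"], a, b
    )
    post_hoc = {
        "control_large_vs_small": lsd(
            {"group": "control", "magnitude": "large"},
            {"group": "control", "magnitude": "small"},
        ),
        "patient_large_vs_small": lsd(
            {"group": "patient", "magnitude": "large"},
            {"group": "patient", "magnitude": "small"},
        ),
        "groups_at_large": lsd(
            {"group": "patient", "magnitude": "large"},
            {"group": "control", "magnitude": "large"},
        ),
        "groups_at_small": lsd(
            {"group": "patient", "magnitude": "small"},
            {"group": "control", "magnitude": "small"},
        ),
    }
    summaries = effect_summaries(auc_table)
    bayes = {
        name: inf.jzs_bf_ttest(
            summaries[name]["patient"], summaries[name]["control"],
            prior_scale=prior_scale,
        )
        for name in ("eft_effect", "magnitude_effect")
    }

    inc_anova = inc_post = None
    if trial_table is not None:
        inc = trial_table.copy()
        if exclude_ids:
            inc = inc[~inc["participant_id"].isin(exclude_ids)]
        if "n_inconsistent" not in inc.columns:
            inc = analyze_svs(choices_to_svs(read_frame(inc)))
        inc_anova = inf.mixed_anova(
            inc, dv="n_inconsistent", between="group",
            within=["condition", "magnitude"],
        )
        inc_lsd = lambda a, b: inf.fisher_lsd(  # noqa: E731
            inc, "n_inconsistent", "group", ["condition", "magnitude"], a, b
        )
        inc_post = {
            "groups_in_standard": inc_lsd(
                {"group": "patient", "condition": "Standard"},
                {"group": "control", "condition": "Standard"},
            ),
            "groups_in_eft": inc_lsd(
                {"group": "patient", "condition": "EFT"},
                {"group": "control", "condition": "EFT"},
            ),
        }

    bundle = ResultsBundle(
        auc_anova=anova,
        post_hoc=post_hoc,
        effect_summaries=summaries,
        bayes=bayes,
        inconsistency_anova=inc_anova,
        inconsistency_post_hoc=inc_post,
        provenance={
            "auc_table_sha256": checksum,
            "n_participants": int(auc_table["participant_id"].nunique()),
            "excluded": list(exclude_ids or []),
            "prior_scale": prior_scale,
        }
        | dict(provenance or {}),
    )
    log.info(
        "reproduce: %d participants, %d ANOVA rows",
        bundle.provenance["n_participants"], len(anova),
    )
    return bundle


def read_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Validate an in-memory choice table as :func:`read_choices` does."""
    import io as _io

    buf = _io.StringIO()
    df.to_csv(buf, index=False)
    buf.seek(0)
    return read_choices(buf)
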