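"""Feature-table assembly: normalization, goal designs, serialization.

A :class:`FeatureTable` holds four delimited-text-friendly frames:

* ``individual`` — one row per (dyad_id, interval_index, participant) with
  the 20 individual features,
* ``synchrony`` — one row per (dyad_id, interval_index) with the 36
  synchrony features,
* ``labels`` — (dyad_id, interval_index, participant, rater) with integer
  1-9 valence/arousal (participant 0 = the dyad-level observer stream),
* ``characteristics`` — (dyad_id, participant) with age, gender and the
  four trait scores.

Design matrices: goals 1 and 2 use a participant's own 20 individual
features plus the dyad's 36 synchrony features (56 columns); goal 3 uses
both participants' individual features plus synchrony (76 columns).
Participant characteristics can be appended for the dyad-nonspecific goals.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from .errors import ConfigurationError, SchemaError
from .individual_features import FEATURE_NAMES as INDIVIDUAL_FEATURE_NAMES
from .synchrony import SYNCHRONY_FEATURE_NAMES
from .types import DyadRecord

logger = logging.getLogger(__name__)

CHARACTERISTIC_NAMES = ("age", "gender", "cognitive_empathy", "affective_empathy",
                        "social_anxiety", "depression")
GENDER_LEVELS = ("female", "male", "nonbinary")
TARGETS = ("valence", "arousal")


@dataclass(frozen=True)
class GoalSpec:
    """One of the three estimation goals.

    Goal 1: dyad-specific, self ratings.  Goal 2: dyad-nonspecific, self
    ratings.  Goal 3: dyad-nonspecific, observer ratings (one per dyad).
    """

    goal: int
    rater: str = ""
    include_characteristics: bool = False

    def __post_init__(self) -> None:
        if self.goal not in (1, 2, 3):
            raise ConfigurationError("goal must be 1, 2 or 3")
        rater = self.rater or ("observer" if self.goal == 3 else "self")
        object.__setattr__(self, "rater", rater)
        if self.goal == 3 and self.rater != "observer":
            raise ConfigurationError("goal 3 uses observer ratings")
        if self.goal in (1, 2) and self.rater != "self":
            raise ConfigurationError("goals 1-2 use self ratings")

    @property
    def dyad_specific(self) -> bool:
        return self.goal == 1


@dataclass
class FeatureTable:
    individual: pd.DataFrame
    synchrony: pd.DataFrame
    labels: pd.DataFrame
    characteristics: pd.DataFrame | None = None
    normalized: bool = False
    n_conversation_intervals: int = 10
    feature_roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.feature_roles:
            roles = {n: "individual" for n in INDIVIDUAL_FEATURE_NAMES}
            roles.update({n: "sync" for n in SYNCHRONY_FEATURE_NAMES})
            roles.update({n: "characteristic" for n in CHARACTERISTIC_NAMES})
            self.feature_roles = roles

    @property
    def dyad_ids(self) -> list[int]:
        return sorted(self.individual["dyad_id"].unique())

    @property
    def conversation_intervals(self) -> range:
        return range(1, self.n_conversation_intervals + 1)


def assemble_table(per_interval_individual: pd.DataFrame,
                   per_interval_synchrony: pd.DataFrame,
                   ratings: pd.DataFrame,
                   characteristics: pd.DataFrame | None = None,
                   n_conversation_intervals: int = 10) -> FeatureTable:
    labels = ratings[["dyad_id", "interval_index", "participant", "rater",
                      "valence", "arousal"]].copy()
    bad = ~labels[list(TARGETS)].isin(range(1, 10)).all(axis=1)
    if bad.any():
        raise SchemaError("labels must be integers in [1, 9]")
    return FeatureTable(individual=per_interval_individual.copy(),
                        synchrony=per_interval_synchrony.copy(),
                        labels=labels, characteristics=characteristics,
                        n_conversation_intervals=n_conversation_intervals)


def table_from_records(records: list[DyadRecord],
                       individual_rows: pd.DataFrame,
                       synchrony_rows: pd.DataFrame) -> FeatureTable:
    ratings = pd.concat([r.ratings.assign(dyad_id=r.dyad_id) for r in records],
                        ignore_index=True)
    chars = pd.concat([r.characteristics.assign(dyad_id=r.dyad_id)
                       for r in records], ignore_index=True)
    return assemble_table(individual_rows, synchrony_rows, ratings, chars,
                          records[0].n_conversation_intervals)


# ---------------------------------------------------------------------------
# baseline normalization

def normalize_by_baseline(table: FeatureTable, mode: str = "first") -> FeatureTable:
    """Subtract each dyad's baseline feature values from its conversation rows.

    ``mode="first"`` subtracts the first baseline interval (index 0);
    ``mode="mean-of-both"`` subtracts the average of both baselines.  Dyads
    with no usable baseline are excluded with a logged warning.  The result
    contains conversation rows only and is flagged to prevent double
    application.
    """
    if table.normalized:
        raise ConfigurationError("feature table is already baseline-normalized")
    if mode not in ("first", "mean-of-both"):
        raise ConfigurationError(f"unknown normalization mode {mode!r}")
    last = table.n_conversation_intervals + 1
    baseline_idx = [0] if mode == "first" else [0, last]
    conv = list(table.conversation_intervals)

    def _norm(df: pd.DataFrame, keys: list[str]) -> pd.DataFrame:
        feats = [c for c in df.columns if c not in keys + ["interval_index"]]
        base = df[df.interval_index.isin(baseline_idx)]
        base = base.groupby(keys, as_index=False)[feats].mean()
        out = df[df.interval_index.isin(conv)].merge(
            base, on=keys, suffixes=("", "__base"), how="left")
        missing = out[feats[0] + "__base"].isna() if feats else pd.Series(dtype=bool)
        dropped = sorted(out.loc[missing, "dyad_id"].unique()) if feats else []
        for d in dropped:
            logger.warning("dyad %s: missing baseline features; excluded", d)
        out = out[~out.dyad_id.isin(dropped)]
        for f in feats:
            out[f] = out[f] - out[f + "__base"]
        return out[df.columns]

    individual = _norm(table.individual, ["dyad_id", "participant"])
    synchrony = _norm(table.synchrony, ["dyad_id"])
    return replace(table, individual=individual, synchrony=synchrony,
                   normalized=True)


# ---------------------------------------------------------------------------
# design matrices

def _one_hot_gender(series: pd.Series, prefix: str) -> pd.DataFrame:
    out = {}
    for level in GENDER_LEVELS:
        out[f"{prefix}gender_{level}"] = (series == level).astype(float).to_numpy()
    return pd.DataFrame(out, index=series.index)


def _characteristic_block(chars: pd.DataFrame, prefix: str = "") -> pd.DataFrame:
    num = chars[["age", "cognitive_empathy", "affective_empathy",
                 "social_anxiety", "depression"]].astype(float)
    num = num.rename(columns={c: prefix + c for c in num.columns})
    gen = _one_hot_gender(chars["gender"], prefix)
    block = pd.concat([num.reset_index(drop=True), gen.reset_index(drop=True)],
                      axis=1)
    block.insert(0, "dyad_id", chars["dyad_id"].to_numpy())
    block.insert(1, "participant", chars["participant"].to_numpy())
    return block


def build_design(table: FeatureTable, goal: GoalSpec, target: str,
                 ) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Assemble (X, y, units) for one goal and target.

    ``units`` carries the crossvalidation unit key per row: (dyad_id,
    participant) for goals 1-2, dyad_id for goal 3, plus interval_index.
    """
    if target not in TARGETS:
        raise ConfigurationError(f"target must be one of {TARGETS}")
    conv = list(table.conversation_intervals)
    sync = table.synchrony[table.synchrony.interval_index.isin(conv)]
    ind = table.individual[table.individual.interval_index.isin(conv)]
    labels = table.labels[(table.labels.rater == goal.rater)
                          & table.labels.interval_index.isin(conv)]

    if goal.goal in (1, 2):
        rows = ind.merge(sync, on=["dyad_id", "interval_index"], how="inner")
        rows = rows.merge(
            labels[["dyad_id", "interval_index", "participant", target]],
            on=["dyad_id", "interval_index", "participant"], how="left")
        if goal.include_characteristics:
            if table.characteristics is None:
                raise ConfigurationError("characteristics not available")
            rows = rows.merge(_characteristic_block(table.characteristics),
                              on=["dyad_id", "participant"], how="left")
        feature_cols = [c for c in rows.columns
                        if c not in ("dyad_id", "interval_index", "participant",
                                     target)]
        unit_cols = ["dyad_id", "participant", "interval_index"]
    else:
        p1 = ind[ind.participant == 1].drop(columns="participant")
        p2 = ind[ind.participant == 2].drop(columns="participant")
        feats = [c for c in p1.columns if c not in ("dyad_id", "interval_index")]
        p1 = p1.rename(columns={c: f"p1_{c}" for c in feats})
        p2 = p2.rename(columns={c: f"p2_{c}" for c in feats})
        rows = p1.merge(p2, on=["dyad_id", "interval_index"], how="inner")
        rows = rows.merge(sync, on=["dyad_id", "interval_index"], how="inner")
        rows = rows.merge(labels[["dyad_id", "interval_index", target]],
                          on=["dyad_id", "interval_index"], how="left")
        if goal.include_characteristics:
            if table.characteristics is None:
                raise ConfigurationError("characteristics not available")
            for p in (1, 2):
                blk = _characteristic_block(
                    table.characteristics[table.characteristics.participant == p],
                    prefix=f"p{p}_").drop(columns="participant")
                rows = rows.merge(blk, on="dyad_id", how="left")
        feature_cols = [c for c in rows.columns
                        if c not in ("dyad_id", "interval_index", target)]
        unit_cols = ["dyad_id", "interval_index"]

    missing = rows[target].isna()
    if missing.any():
        logger.warning("%d rows dropped for missing %s labels",
                       int(missing.sum()), target)
        rows = rows[~missing]
    X = rows[feature_cols].reset_index(drop=True)
    y = rows[target].astype(float).reset_index(drop=True)
    units = rows[unit_cols].reset_index(drop=True)
    return X, y, units


# ---------------------------------------------------------------------------
# serialization and the deposited-tables path

def save_table(table: FeatureTable, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.individual.to_csv(out / "individual_features.csv", index=False)
    table.synchrony.to_csv(out / "synchrony_features.csv", index=False)
    table.labels.to_csv(out / "labels.csv", index=False)
    if table.characteristics is not None:
        table.characteristics.to_csv(out / "characteristics.csv", index=False)
    schema = {"normalized": table.normalized,
              "n_conversation_intervals": table.n_conversation_intervals,
              "feature_roles": table.feature_roles}
    (out / "schema.json").write_text(json.dumps(schema, indent=1))


def load_table(in_dir: str | Path) -> FeatureTable:
    in_dir = Path(in_dir)
    schema = json.loads((in_dir / "schema.json").read_text())
    chars_path = in_dir / "characteristics.csv"
    return FeatureTable(
        individual=pd.read_csv(in_dir / "individual_features.csv"),
        synchrony=pd.read_csv(in_dir / "synchrony_features.csv"),
        labels=pd.read_csv(in_dir / "labels.csv"),
        characteristics=pd.read_csv(chars_path) if chars_path.exists() else None,
        normalized=schema["normalized"],
        n_conversation_intervals=schema["n_conversation_intervals"],
        feature_roles=schema["feature_roles"])


REQUIRED_RATING_COLUMNS = ("dyad_id", "interval_index", "participant", "rater",
                           "valence", "arousal")


def load_deposited_tables(features_path: str | Path, ratings_path: str | Path,
                          column_map: dict[str, str] | None = None,
                          characteristics_path: str | Path | None = None,
                          n_conversation_intervals: int = 10) -> FeatureTable:
    """Load externally deposited extracted-feature and rating tables.

    ``column_map`` maps columns of the deposited delimited-text files onto
    canonical names (the 20 individual and 36 synchrony feature names, the
    key columns and valence/arousal).  No signal processing is performed.
    Raises :class:`SchemaError` naming any unmapped required column.
    """
    column_map = column_map or {}
    feats = pd.read_csv(features_path).rename(columns=column_map)
    ratings = pd.read_csv(ratings_path).rename(columns=column_map)
    missing = [c for c in REQUIRED_RATING_COLUMNS if c not in ratings.columns]
    key_missing = [c for c in ("dyad_id", "interval_index") if c not in feats.columns]
    if missing or key_missing:
        raise SchemaError(f"unmapped required columns: ratings {missing}, "
                          f"features {key_missing}")
    ind_cols = [c for c in INDIVIDUAL_FEATURE_NAMES if c in feats.columns]
    sync_cols = [c for c in SYNCHRONY_FEATURE_NAMES if c in feats.columns]
    if not ind_cols and not sync_cols:
        raise SchemaError("no recognizable feature columns after mapping")
    keys_ind = ["dyad_id", "interval_index"] + (
        ["participant"] if "participant" in feats.columns else [])
    individual = feats[keys_ind + ind_cols]
    synchrony = feats[["dyad_id", "interval_index"] + sync_cols].drop_duplicates(
        subset=["dyad_id", "interval_index"])
    chars = (pd.read_csv(characteristics_path).rename(columns=column_map)
             if characteristics_path else None)
    return assemble_table(individual, synchrony, ratings, chars,
                          n_conversation_intervals)
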