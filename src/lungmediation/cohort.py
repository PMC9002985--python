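"""Cohort data model, file I/O, variable coding and descriptive summaries.

The unit of analysis is the adult offspring; each offspring row carries its
parent's identifier (the family cluster used for resampling), the parental
line (paternal/maternal), the three-level parental-overweight exposure,
the offspring's own prepubertal-overweight mediator, measured adult height,
spirometric outcomes and the covariates (parental education, offspring age
and smoking history).

Overweight at a life stage is coded from a nine-level figural drawing scale
(sex-specific body silhouettes): scores of five or greater indicate
overweight for males, four or greater for females. The exposure category is
derived from the three life-stage flags: overweight *before puberty* means
overweight at age 8 and/or in puberty; *at 30 but not before* means
overweight at age 30 only; otherwise *never*.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .coefficients import EXPOSURE_LEVELS, GROUPS, LINES
from .util import round_half_away

logger = logging.getLogger(__name__)

SILHOUETTE_STAGES = ("age8", "puberty", "age30")

#: canonical on-disk column order
COLUMNS = (
    "offspring_id", "parent_id", "line", "sex", "age", "ever_smoker",
    "m1_overweight_prepuberty", "height_cm", "fev1_ml", "fvc_ml",
    "fev1_post_ml", "fvc_post_ml", "parent_edu_low", "parent_exposure",
)
OPTIONAL_COLUMNS = ("fev1_post_ml", "fvc_post_ml")
MANDATORY_COLUMNS = tuple(c for c in COLUMNS if c not in OPTIONAL_COLUMNS)
BOOL_COLUMNS = ("ever_smoker", "m1_overweight_prepuberty", "parent_edu_low")

# record-level plausibility windows
AGE_MIN = 18.0
HEIGHT_RANGE = (120.0, 230.0)
LUNG_RANGE = (500.0, 9000.0)


class CohortError(ValueError):
    """Hard validation failure (schema, uniqueness, emptiness)."""


@dataclass(frozen=True)
class SilhouetteReport:
    """Self-reported body silhouettes (1-9) at the three life stages."""

    sex: str  # "male" | "female"
    score_age8: int
    score_puberty: int
    score_age30: int

    def score(self, stage: str) -> int:
        if stage not in SILHOUETTE_STAGES:
            raise CohortError(f"unknown life stage {stage!r}")
        return getattr(self, f"score_{stage}")


@dataclass
class CohortTable:
    """Validated offspring-level table plus a provenance note."""

    df: pd.DataFrame
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, mask) -> "CohortTable":
        return CohortTable(self.df.loc[mask].reset_index(drop=True), self.provenance)

    def for_line(self, line: str) -> "CohortTable":
        if line not in LINES:
            raise CohortError(f"unknown line {line!r}")
        return self.subset(self.df["line"] == line)

    @property
    def parent_ids(self) -> np.ndarray:
        return self.df["parent_id"].unique()

    def with_column(self, name: str, values) -> "CohortTable":
        df = self.df.copy()
        df[name] = np.asarray(values)
        return CohortTable(df, self.provenance)


# ---------------------------------------------------------------------------
# variable coding
# ---------------------------------------------------------------------------

def code_overweight_from_silhouette(report: SilhouetteReport, stage: str) -> bool:
    """Overweight flag at one life stage from the figural drawing score.

    Cut-offs: score >= 5 for males, >= 4 for females.
    """
    if report.sex not in ("male", "female"):
        raise CohortError(f"unknown sex {report.sex!r}")
    score = report.score(stage)
    if not (1 <= score <= 9):
        raise CohortError(f"silhouette score {score} outside 1..9")
    cutoff = 5 if report.sex == "male" else 4
    return score >= cutoff


def derive_exposure_category(ow_age8, ow_puberty, ow_age30) -> str:
    """Three-level exposure from the life-stage overweight flags.

    ``before_puberty`` if overweight at age 8 and/or in puberty;
    ``at30_not_before`` if overweight at 30 only; else ``never``.
    A missing flag raises; the reader converts that into a logged drop.
    """
    flags = (ow_age8, ow_puberty, ow_age30)
    if any(f is None or (isinstance(f, float) and np.isnan(f)) for f in flags):
        raise CohortError("missing overweight flag")
    ow_age8, ow_puberty, ow_age30 = (bool(f) for f in flags)
    if ow_age8 or ow_puberty:
        return "before_puberty"
    if ow_age30:
        return "at30_not_before"
    return "never"


def _line_parent_sex(line: str) -> str:
    return "male" if line == "paternal" else "female"


def _offspring_sex(group: str) -> str:
    return "male" if group == "son" else "female"


# ---------------------------------------------------------------------------
# schema configuration
# ---------------------------------------------------------------------------

@dataclass
class SchemaConfig:
    """Column-name mapping and delimiter for external files.

    ``columns`` maps canonical names (see :data:`COLUMNS`, plus the optional
    silhouette-score columns ``parent_score_age8``, ``parent_score_puberty``,
    ``parent_score_age30``, ``offspring_score_age8``,
    ``offspring_score_puberty``) to the names used in the file.
    """

    columns: dict = field(default_factory=dict)
    delimiter: str = ","

    def external(self, canonical: str) -> str:
        return self.columns.get(canonical, canonical)

    @classmethod
    def from_file(cls, path) -> "SchemaConfig":
        text = open(path).read()
        payload = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) \
            else json.loads(text)
        return cls(**(payload or {}))


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def _to_bool(series: pd.Series) -> pd.Series:
    mapping = {"0": False, "1": True, "false": False, "true": True,
               0: False, 1: True, False: False, True: True,
               0.0: False, 1.0: True}

    def conv(v):
        if pd.isna(v) or v == "":
            return np.nan
        key = v.strip().lower() if isinstance(v, str) else v
        if key not in mapping:
            raise CohortError(f"cannot interpret boolean value {v!r}")
        return mapping[key]

    return series.map(conv)


def _derive_parent_exposure(df: pd.DataFrame, schema: SchemaConfig, drops: dict):
    """Fill parent_exposure from parental silhouette scores where absent."""
    score_cols = [schema.external(f"parent_score_{s}") for s in SILHOUETTE_STAGES]
    if not all(c in df.columns for c in score_cols):
        return df
    if "parent_exposure" in df.columns and df["parent_exposure"].notna().all():
        logger.warning("both parental silhouette scores and pre-coded exposure "
                       "present; pre-coded flags win")
        return df
    derived = []
    for _, row in df.iterrows():
        pre = row.get("parent_exposure")
        if isinstance(pre, str) and pre in EXPOSURE_LEVELS:
            derived.append(pre)
            continue
        try:
            sex = _line_parent_sex(row["line"])
            rep = SilhouetteReport(sex, *(int(row[c]) for c in score_cols))
            flags = [code_overweight_from_silhouette(rep, s) for s in SILHOUETTE_STAGES]
            derived.append(derive_exposure_category(*flags))
        except (CohortError, ValueError, TypeError):
            derived.append(np.nan)
    df = df.copy()
    df["parent_exposure"] = derived
    return df


def _derive_offspring_m1(df: pd.DataFrame, schema: SchemaConfig):
    score_cols = [schema.external(f"offspring_score_{s}") for s in ("age8", "puberty")]
    if not all(c in df.columns for c in score_cols):
        return df
    if "m1_overweight_prepuberty" in df.columns and \
            df["m1_overweight_prepuberty"].notna().all():
        logger.warning("both offspring silhouette scores and pre-coded overweight "
                       "flag present; pre-coded flags win")
        return df
    derived = []
    for _, row in df.iterrows():
        pre = row.get("m1_overweight_prepuberty")
        if pre is not None and not pd.isna(pre):
            derived.append(bool(pre))
            continue
        try:
            sex = _offspring_sex(row["sex"])
            scores = [int(row[c]) for c in score_cols]
            rep = SilhouetteReport(sex, scores[0], scores[1], scores[1])
            derived.append(code_overweight_from_silhouette(rep, "age8")
                           or code_overweight_from_silhouette(rep, "puberty"))
        except (CohortError, ValueError, TypeError):
            derived.append(np.nan)
    df = df.copy()
    df["m1_overweight_prepuberty"] = derived
    return df


def read_cohort(path, schema: SchemaConfig | None = None) -> CohortTable:
    """Read, type and validate a delimited cohort file.

    Rows failing completeness or plausibility checks are dropped, with one
    logged ``DROPPED <n> rows: <reason>`` line per reason (complete-case
    analysis; no imputation). Missing mandatory columns, an empty file, a
    duplicated offspring id, or a parent appearing in both lines are hard
    errors.
    """
    schema = schema or SchemaConfig()
    df = pd.read_csv(path, sep=schema.delimiter, dtype=str,
                     keep_default_na=False)
    if df.empty:
        raise CohortError(f"empty cohort file: {path}")
    rename = {schema.external(c): c for c in COLUMNS if schema.external(c) in df.columns}
    df = df.rename(columns=rename)
    df = df.mask(df == "")

    # silhouette-derived codings (before the mandatory-column check, since
    # exposure/mediator may legitimately arrive only as silhouette scores)
    for col in ("line", "sex"):
        if col not in df.columns:
            raise CohortError(f"missing mandatory column {col!r}")
    drops: dict[str, int] = {}
    df = _derive_parent_exposure(df, schema, drops)
    df = _derive_offspring_m1(df, schema)

    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise CohortError(f"missing mandatory column(s): {', '.join(missing)}")
    for col in OPTIONAL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan

    # typing
    for col in ("age", "height_cm", "fev1_ml", "fvc_ml", "fev1_post_ml", "fvc_post_ml"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in BOOL_COLUMNS:
        df[col] = _to_bool(df[col])

    def drop(mask: pd.Series, reason: str):
        nonlocal df
        n = int(mask.sum())
        if n:
            drops[reason] = drops.get(reason, 0) + n
            df = df.loc[~mask]

    drop(df["parent_exposure"].isna() |
         ~df["parent_exposure"].isin(EXPOSURE_LEVELS), "missing or invalid exposure")
    drop(~df["sex"].isin(GROUPS), "invalid sex")
    drop(~df["line"].isin(LINES), "invalid line")
    for col, label in (("m1_overweight_prepuberty", "missing overweight mediator"),
                       ("ever_smoker", "missing smoking history"),
                       ("parent_edu_low", "missing parental education")):
        drop(df[col].isna(), label)
    drop(df["age"].isna() | (df["age"] < AGE_MIN), "missing or implausible age")
    drop(df["height_cm"].isna() |
         ~df["height_cm"].between(*HEIGHT_RANGE, inclusive="neither"),
         "missing or implausible height")
    for col in ("fev1_ml", "fvc_ml"):
        drop(df[col].isna() | ~df[col].between(*LUNG_RANGE, inclusive="neither"),
             f"missing or implausible {col}")

    # post-bronchodilator values are kept only as a complete pair
    half_post = df["fev1_post_ml"].isna() != df["fvc_post_ml"].isna()
    if half_post.any():
        logger.warning("BLANKED %d incomplete post-bronchodilator pairs",
                       int(half_post.sum()))
        df.loc[half_post, ["fev1_post_ml", "fvc_post_ml"]] = np.nan
    bad_post = df["fev1_post_ml"].notna() & (
        ~df["fev1_post_ml"].between(*LUNG_RANGE, inclusive="neither") |
        ~df["fvc_post_ml"].between(*LUNG_RANGE, inclusive="neither"))
    if bad_post.any():
        logger.warning("BLANKED %d implausible post-bronchodilator pairs",
                       int(bad_post.sum()))
        df.loc[bad_post, ["fev1_post_ml", "fvc_post_ml"]] = np.nan

    for reason, n in drops.items():
        logger.info("DROPPED %d rows: %s", n, reason)

    if df.empty:
        raise CohortError("no valid rows after validation")
    if df["offspring_id"].duplicated().any():
        dupes = df.loc[df["offspring_id"].duplicated(), "offspring_id"].tolist()
        raise CohortError(f"duplicate offspring_id values: {dupes[:5]}")
    lines_per_parent = df.groupby("parent_id")["line"].nunique()
    if (lines_per_parent > 1).any():
        raise CohortError("a parent_id appears in more than one line")

    for col in BOOL_COLUMNS:
        df[col] = df[col].astype(bool)
    df = df[list(COLUMNS)].reset_index(drop=True)
    return CohortTable(df, provenance=f"file:{path}")


def write_cohort(table: CohortTable, path, schema: SchemaConfig | None = None) -> None:
    """Write a cohort table; booleans as 0/1, enums as lowercase strings.

    Column order is fixed by the schema configuration, so that
    ``read_cohort(write_cohort(T))`` round-trips values exactly.
    """
    schema = schema or SchemaConfig()
    df = table.df.copy()
    extra = [c for c in df.columns if c not in COLUMNS]
    for col in BOOL_COLUMNS:
        df[col] = df[col].astype(int)
    df = df[list(COLUMNS) + extra]
    df = df.rename(columns={c: schema.external(c) for c in COLUMNS})
    df.to_csv(path, sep=schema.delimiter, index=False)


# ---------------------------------------------------------------------------
# descriptive summaries
# ---------------------------------------------------------------------------

@dataclass
class SummaryTable:
    """Tidy descriptive summary: one row per generation x statistic x group."""

    df: pd.DataFrame
    line: str

    def get(self, generation: str, statistic: str, group: str = "total") -> float:
        rows = self.df[(self.df.generation == generation) &
                       (self.df.statistic == statistic) &
                       (self.df.group == group)]
        if rows.empty:
            raise KeyError((generation, statistic, group))
        return float(rows["value"].iloc[0])


def _pct(count: int, n: int) -> float:
    return round_half_away(100.0 * count / n, 1)


def summarize_cohort(table: CohortTable, line: str, by: str = "sex") -> SummaryTable:
    """Descriptive summary of one line, overall and by offspring sex.

    Prevalences are percentages rounded half-away-from-zero to one decimal
    with the raw counts alongside; age is summarised by median and range,
    continuous measures by mean and sd. Parent counts in the sex-specific
    columns are counts of distinct parents with at least one offspring of
    that sex (a parent with offspring of both sexes contributes to both).
    """
    if by != "sex":
        raise CohortError(f"unsupported moderator {by!r}")
    sub = table.for_line(line)
    if len(sub) == 0:
        raise CohortError(f"no records for line {line!r}")

    rows = []

    def add(generation, statistic, group, value, count=None):
        rows.append({"generation": generation, "statistic": statistic,
                     "group": group, "value": value, "count": count})

    groupings = [("total", sub.df)] + [
        (g, sub.df[sub.df.sex == g]) for g in GROUPS]
    for group, df in groupings:
        if df.empty:
            raise CohortError(f"empty group {group!r} in line {line!r}")
        parents = df.drop_duplicates("parent_id")
        n_par = len(parents)
        add("parent", "n", group, n_par)
        add("parent", "edu_low_pct", group,
            _pct(int(parents.parent_edu_low.sum()), n_par),
            int(parents.parent_edu_low.sum()))
        counts = {lvl: int((parents.parent_exposure == lvl).sum())
                  for lvl in EXPOSURE_LEVELS}
        assert sum(counts.values()) == n_par
        for lvl in EXPOSURE_LEVELS:
            add("parent", f"exposure_{lvl}_pct", group,
                _pct(counts[lvl], n_par), counts[lvl])

        n_off = len(df)
        add("offspring", "n", group, n_off)
        add("offspring", "age_median", group, float(df.age.median()))
        add("offspring", "age_min", group, float(df.age.min()))
        add("offspring", "age_max", group, float(df.age.max()))
        for col, label in (("height_cm", "height"), ("fev1_ml", "fev1"),
                           ("fvc_ml", "fvc")):
            add("offspring", f"{label}_mean", group, float(df[col].mean()))
            add("offspring", f"{label}_sd", group, float(df[col].std(ddof=1))
                if n_off > 1 else 0.0)
        ratio = 100.0 * df.fev1_ml / df.fvc_ml
        add("offspring", "fev1_fvc_mean", group, float(ratio.mean()))
        add("offspring", "fev1_fvc_sd", group,
            float(ratio.std(ddof=1)) if n_off > 1 else 0.0)
        post = df[df.fev1_post_ml.notna()]
        add("offspring", "n_post", group, len(post))
        for col, label in (("fev1_post_ml", "fev1_post"), ("fvc_post_ml", "fvc_post")):
            if len(post):
                add("offspring", f"{label}_mean", group, float(post[col].mean()))
                add("offspring", f"{label}_sd", group,
                    float(post[col].std(ddof=1)) if len(post) > 1 else 0.0)
        add("offspring", "overweight_prepuberty_pct", group,
            _pct(int(df.m1_overweight_prepuberty.sum()), n_off),
            int(df.m1_overweight_prepuberty.sum()))
        add("offspring", "ever_smoking_pct", group,
            _pct(int(df.ever_smoker.sum()), n_off), int(df.ever_smoker.sum()))

    return SummaryTable(pd.DataFrame(rows), line=line)
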