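"""File formats: quarterly tables, taxonomy edge lists, configs, reports.

Quarterly tables are comma-separated with a header.  List-valued fields
(drugs, sensitive terms) are semicolon-joined; numeric QID values are
serialized as ``lo-hi`` intervals (a bare number when degenerate) and
categorical values by their taxonomy label.  Released tables additionally
carry ``leaf_<attr>`` columns with the true leaf values so a series can be
audited after a round trip.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from .anonymize import SuppressionLog
from .attacks import AttackFinding
from .model import AttributeSchema, QIDValue, Schema, SRSRecord, make_qid
from .privacy import PrivacyParams, ThresholdMap
from .series import PublishedRecord, Release, ReleaseSeries
from .taxonomy import TaxonomyTree


class ValidationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# QID serialization
# ---------------------------------------------------------------------------


def format_qid_value(attr: AttributeSchema, v) -> str:
    if attr.kind == "numeric":
        lo, hi = v
        if lo == hi:
            return f"{lo:g}"
        return f"{lo:g}-{hi:g}"
    return str(v)


def parse_qid_value(attr: AttributeSchema, s: str):
    s = str(s).strip()
    if attr.kind == "categorical":
        return s
    # numeric: "lo-hi" or a bare number (nonnegative dialect)
    if "-" in s[1:]:
        cut = s.index("-", 1)
        try:
            return (float(s[:cut]), float(s[cut + 1:]))
        except ValueError as e:
            raise ValidationError(f"{attr.name}: bad interval {s!r}") from e
    try:
        x = float(s)
    except ValueError as e:
        raise ValidationError(f"{attr.name}: bad numeric value {s!r}") from e
    return (x, x)


def _join(items) -> str:
    return ";".join(sorted(items))


def _split(s) -> frozenset[str]:
    if pd.isna(s) or s == "":
        return frozenset()
    return frozenset(str(s).split(";"))


# ---------------------------------------------------------------------------
# Raw quarterly tables
# ---------------------------------------------------------------------------


def write_raw_quarter(path, schema: Schema, records: list[SRSRecord]) -> None:
    rows = []
    for r in records:
        row = {"case_id": r.case_id, "quarter": r.quarter}
        for attr, v in zip(schema, r.qid):
            row[attr.name] = format_qid_value(attr, v)
        row["drugs"] = _join(r.drugs)
        row["sensitive"] = _join(r.sensitive)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_raw_quarter(path, schema: Schema, *, drop_missing: bool = True) -> list[SRSRecord]:
    """Load one raw quarter.  Rows with a missing QID or sensitive field are
    dropped (reports lacking them cannot be anonymized or audited)."""
    df = pd.read_csv(path, dtype=str).fillna("")
    needed = ["case_id", "quarter"] + [a.name for a in schema] + ["sensitive"]
    for col in needed:
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    out = []
    for idx, row in df.iterrows():
        missing = any(row[a.name] == "" for a in schema) or row["sensitive"] == ""
        if missing:
            if drop_missing:
                continue
            raise ValidationError(f"{path}: row {idx + 2}: missing value")
        try:
            qid = make_qid(schema, [parse_qid_value(a, row[a.name]) for a in schema])
        except (ValidationError, ValueError) as e:
            raise ValidationError(f"{path}: row {idx + 2}: {e}") from e
        out.append(SRSRecord(
            case_id=int(row["case_id"]), quarter=int(row["quarter"]), qid=qid,
            drugs=_split(row.get("drugs", "")), sensitive=_split(row["sensitive"])))
    return out


# ---------------------------------------------------------------------------
# Released tables
# ---------------------------------------------------------------------------


def write_release(path, schema: Schema, release: Release) -> None:
    rows = []
    for r in release.records:
        row = {"case_id": r.case_id, "quarter": r.quarter}
        for attr, v in zip(schema, r.qid):
            row[attr.name] = format_qid_value(attr, v)
        row["drugs"] = _join(r.drugs)
        row["sensitive"] = _join(r.sensitive)
        if r.leaf_qid is not None:
            for attr, v in zip(schema, r.leaf_qid):
                row[f"leaf_{attr.name}"] = format_qid_value(attr, v)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_release(path, schema: Schema) -> Release:
    df = pd.read_csv(path, dtype=str).fillna("")
    has_leaf = all(f"leaf_{a.name}" in df.columns for a in schema)
    records, quarter = [], 1
    for _, row in df.iterrows():
        quarter = int(row["quarter"])
        qid = make_qid(schema, [parse_qid_value(a, row[a.name]) for a in schema])
        leaf = None
        if has_leaf:
            leaf = make_qid(schema, [parse_qid_value(a, row[f"leaf_{a.name}"]) for a in schema])
        records.append(PublishedRecord(
            case_id=int(row["case_id"]), quarter=quarter, qid=qid,
            drugs=_split(row.get("drugs", "")), sensitive=_split(row["sensitive"]),
            leaf_qid=leaf))
    return Release(quarter=quarter, records=records)


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


def write_audit_report(path, findings: list[AttackFinding]) -> None:
    rows = []
    for f in findings:
        term, conf = f.max_confidence()
        rows.append({
            "release": f.release_index + 1,
            "case_id": f.case_id,
            "ci_size": len(f.ci),
            "b_size": len(f.b_set),
            "f_size": len(f.f_set),
            "l_size": len(f.l_set),
            "effective_size": f.effective_anonymity,
            "max_confidence": round(conf, 6),
            "max_confidence_term": term or "",
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def write_suppression_log(path, log: SuppressionLog) -> None:
    rows = [{"quarter": q, "case_id": cid, "reason": reason}
            for q, cid, reason in log.suppressed]
    for q, terms in log.infeasible_terms.items():
        for t in terms:
            rows.append({"quarter": q, "case_id": "", "reason": f"infeasible term: {t}"})
    pd.DataFrame(rows, columns=["quarter", "case_id", "reason"]).to_csv(path, index=False)


def write_thresholds(path, thresholds: ThresholdMap) -> None:
    rows = [{"term": t, "theta": th} for t, th in sorted(thresholds.items())]
    pd.DataFrame(rows, columns=["term", "theta"]).to_csv(path, index=False, sep="\t")


def read_thresholds(path, default: float = 1.0) -> ThresholdMap:
    df = pd.read_csv(path, sep="\t")
    return ThresholdMap(thresholds={str(r["term"]): float(r["theta"]) for _, r in df.iterrows()},
                        default=default)


def read_levels(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return {str(r["term"]): str(r["level"]) for _, r in df.iterrows()}


def read_rules(path):
    """Rules file: CSV with drug, reaction, attribute, op, value."""
    from .signals import ADRRule

    df = pd.read_csv(path, dtype=str)
    return [ADRRule(drug=r["drug"], reaction=r["reaction"], attribute=r["attribute"],
                    op=r["op"], value=r["value"]) for _, r in df.iterrows()]


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RunConfig:
    schema: Schema
    variant: str
    k: int
    lifespan_x: int
    seed: int
    threshold_mode: str                 # uniform | frequency | levelwise | file
    theta: float | None = None          # uniform
    levels_path: str | None = None      # levelwise
    thresholds_path: str | None = None  # file


def load_config(path) -> RunConfig:
    base = Path(path).parent
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    try:
        attrs = []
        for a in doc["schema"]:
            if a["kind"] == "numeric":
                attrs.append(AttributeSchema(name=a["name"], kind="numeric",
                                             global_min=float(a["min"]),
                                             global_max=float(a["max"])))
            else:
                tax_path = Path(a["taxonomy"])
                if not tax_path.is_absolute():
                    tax_path = base / tax_path
                attrs.append(AttributeSchema(name=a["name"], kind="categorical",
                                             taxonomy=TaxonomyTree.load(tax_path)))
        priv = doc["privacy"]
        th = priv.get("thresholds", {"mode": "uniform", "theta": 1.0})
        k = int(priv["k"])
        if k < 2:
            raise ValidationError("k must be >= 2")
        return RunConfig(
            schema=tuple(attrs),
            variant=doc.get("variant", "ppms++"),
            k=k,
            lifespan_x=int(priv.get("lifespan", 8)),
            seed=int(doc.get("seed", 0)),
            threshold_mode=th["mode"],
            theta=float(th["theta"]) if "theta" in th else None,
            levels_path=str(base / th["levels_file"]) if "levels_file" in th else None,
            thresholds_path=str(base / th["thresholds_file"]) if "thresholds_file" in th else None,
        )
    except KeyError as e:
        raise ValidationError(f"{path}: missing config key {e}") from e


def resolve_thresholds(cfg: RunConfig, quarters: list[list[SRSRecord]]
                       ) -> tuple[PrivacyParams, list[ThresholdMap] | None]:
    """Build PrivacyParams and, for the frequency scheme, the per-quarter
    threshold maps derived from each quarter's term counts."""
    from .anonymize import term_counts
    from .privacy import set_thresholds

    per_quarter = None
    if cfg.threshold_mode == "uniform":
        tmap = ThresholdMap.uniform(cfg.theta if cfg.theta is not None else 1.0)
    elif cfg.threshold_mode == "frequency":
        per_quarter = [set_thresholds(term_counts(cfg.schema, q) or {"_": 1}, "frequency")
                       for q in quarters]
        tmap = per_quarter[0]
    elif cfg.threshold_mode == "levelwise":
        levels = read_levels(cfg.levels_path)
        counts = {}
        for q in quarters:
            for r in q:
                for s in r.sensitive:
                    counts[s] = counts.get(s, 0) + 1
        tmap = set_thresholds(counts or {"_": 1}, "levelwise", levels=levels)
    elif cfg.threshold_mode == "file":
        tmap = read_thresholds(cfg.thresholds_path)
    else:
        raise ValidationError(f"unknown threshold mode {cfg.threshold_mode!r}")
    params = PrivacyParams(k=cfg.k, thresholds=tmap,
                           lifespan_x=cfg.lifespan_x, rng_seed=cfg.seed)
    return params, per_quarter


def read_series(paths, schema: Schema) -> ReleaseSeries:
    return ReleaseSeries(schema=schema, releases=[read_release(p, schema) for p in paths])
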