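"""Delimited-text interchange, YAML configuration and run manifests.

TSV is the canonical interchange format (metabolite names such as
"TAG 48:4/18:2" contain commas).  Feature tables carry the metadata
columns ``sample_id``, ``batch``, ``run_order``, ``is_qc`` before the
feature columns; missing abundances are written as empty fields.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .preprocess import PreprocessConfig
from .synthetic import META_COLUMNS, CohortConfig, CohortTable, FeatureMatrix

__all__ = [
    "read_feature_table",
    "write_feature_table",
    "read_cohort",
    "write_cohort",
    "write_truth",
    "write_imputation_set",
    "read_imputation_set",
    "load_config",
    "RunManifest",
    "orchestrate",
]

log = logging.getLogger(__name__)


class TableFormatError(ValueError):
    pass


def write_feature_table(matrix: FeatureMatrix, path: str | Path) -> Path:
    path = Path(path)
    matrix.data.to_csv(path, sep="\t", na_rep="", index=True)
    return path


def read_feature_table(path: str | Path, platform: str | None = None) -> FeatureMatrix:
    """Read a platform TSV back into a :class:`FeatureMatrix`.

    Validates structure eagerly: ragged rows, duplicate feature names,
    duplicate sample ids and non-numeric abundances all fail with the
    offending line or column named.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        n_cols = len(header)
        for lineno, line in enumerate(fh, start=2):
            if len(line.rstrip("\n").split("\t")) != n_cols:
                raise TableFormatError(f"{path}: ragged row at line {lineno}")
    names = header[1:]
    expected_meta = list(META_COLUMNS[1:])
    if names[: len(expected_meta)] != expected_meta:
        raise TableFormatError(
            f"{path}: expected metadata columns {expected_meta}, got {names[:3]}"
        )
    feats = names[len(expected_meta):]
    dupes = pd.Index(feats)[pd.Index(feats).duplicated()].unique().tolist()
    if dupes:
        raise TableFormatError(f"{path}: duplicate feature columns {dupes}")

    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise TableFormatError(f"{path}: duplicate sample ids {dup}")
    for c in feats:
        if not pd.api.types.is_numeric_dtype(df[c]):
            bad = df.index[pd.to_numeric(df[c], errors="coerce").isna()
                           & df[c].notna()][:3].tolist()
            raise TableFormatError(
                f"{path}: non-numeric abundance in column {c!r} (rows {bad})"
            )
    df.index.name = "sample_id"
    return FeatureMatrix(platform or path.stem, df)


def write_cohort(cohort: CohortTable, path: str | Path) -> Path:
    path = Path(path)
    cohort.participants.to_csv(path, sep="\t", na_rep="")
    return path


def read_cohort(path: str | Path) -> CohortTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CohortTable(df)


def write_truth(matrices: list[FeatureMatrix], path: str | Path) -> Path:
    """Write the generator's signal-feature sidecar (never analysis input)."""
    rows = [m.truth for m in matrices if m.truth is not None]
    path = Path(path)
    if rows:
        pd.concat(rows, ignore_index=True).to_csv(path, sep="\t", index=False)
    else:
        pd.DataFrame(
            columns=["feature", "outcome", "log_mean_shift", "effect_size_sd"]
        ).to_csv(path, sep="\t", index=False)
    return path


def write_imputation_set(imp, prefix: str | Path) -> list[Path]:
    """Serialize m completed datasets as suffixed TSVs plus a provenance mask.

    ``<prefix>_imp<i>.tsv`` holds completed copy i (1-based);
    ``<prefix>_mask.tsv`` flags which entries were imputed.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, df in enumerate(imp.datasets, start=1):
        p = prefix.with_name(f"{prefix.name}_imp{i}.tsv")
        df.to_csv(p, sep="\t", na_rep="")
        paths.append(p)
    p = prefix.with_name(f"{prefix.name}_mask.tsv")
    imp.mask.astype(int).to_csv(p, sep="\t")
    paths.append(p)
    return paths


def read_imputation_set(prefix: str | Path):
    """Load an imputation set written by :func:`write_imputation_set`."""
    from .mice import ImputationSet

    prefix = Path(prefix)
    datasets = []
    i = 1
    while True:
        p = prefix.with_name(f"{prefix.name}_imp{i}.tsv")
        if not p.exists():
            break
        datasets.append(pd.read_csv(p, sep="\t", index_col=0))
        i += 1
    if not datasets:
        raise FileNotFoundError(f"no {prefix.name}_imp*.tsv files found")
    mask = pd.read_csv(
        prefix.with_name(f"{prefix.name}_mask.tsv"), sep="\t", index_col=0
    ).astype(bool)
    return ImputationSet(datasets, mask)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def load_config(path: str | Path):
    """Build a :class:`~metarisk.evaluation.StudyConfig` from one YAML document.

    Top-level keys ``cohort`` and ``preprocess`` map onto their config
    dataclasses; remaining keys map onto study-level settings.  A seed is
    mandatory.
    """
    from .evaluation import StudyConfig

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "seed" not in raw:
        raise ValueError("config must set an explicit seed")
    cohort_kw = dict(raw.pop("cohort", {}))
    cohort_kw.setdefault("seed", raw["seed"])
    if "platform_sizes" in cohort_kw:
        cohort_kw["platform_sizes"] = dict(cohort_kw["platform_sizes"])
    pre_kw = dict(raw.pop("preprocess", {}))
    known = {f.name for f in dataclasses.fields(StudyConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("outcomes", "platforms", "feature_sets", "procedures"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    return StudyConfig(
        cohort=CohortConfig(**cohort_kw),
        preprocess=PreprocessConfig(**pre_kw),
        **raw,
    )


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    config: dict
    seed: int
    stages: list[str] = field(default_factory=list)
    artifacts: dict[str, str] = field(default_factory=dict)  # path -> sha256
    started: float = field(default_factory=time.time)
    finished: float | None = None

    def add(self, path: Path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.artifacts[str(path)] = digest

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        payload = dataclasses.asdict(self)
        path.write_text(json.dumps(payload, indent=2, default=str))
        return path


def _config_snapshot(config) -> dict:
    d = dataclasses.asdict(config)
    d["cohort"]["platform_sizes"] = dict(d["cohort"]["platform_sizes"])
    return d


def orchestrate(config, outdir: str | Path) -> RunManifest:
    """Run generate -> preprocess -> evaluate, writing artifacts and a manifest.

    Any stage failure halts the run with the failing stage named.
    Reruns with identical configuration produce identical digests for the
    deterministic stages.
    """
    from .evaluation import run_study
    from .preprocess import preprocess_platform
    from .reporting import write_reports
    from .synthetic import generate_cohort

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(_config_snapshot(config), config.seed)

    try:
        cohort, matrices = generate_cohort(config.cohort)
        manifest.add(write_cohort(cohort, outdir / "cohort.tsv"))
        for m in matrices:
            manifest.add(write_feature_table(m, outdir / f"features_{m.platform}.tsv"))
        manifest.add(write_truth(matrices, outdir / "truth.tsv"))
        manifest.stages.append("generate")
    except Exception as exc:
        raise RuntimeError(f"stage 'generate' failed: {exc}") from exc

    try:
        for m in matrices:
            pm = preprocess_platform(m, config.preprocess)
            log.info("preprocess %s: %d -> %d features", m.platform,
                     len(m.feature_columns), len(pm.feature_columns))
            manifest.add(
                write_feature_table(pm, outdir / f"processed_{m.platform}.tsv")
            )
        manifest.stages.append("preprocess")
    except Exception as exc:
        raise RuntimeError(f"stage 'preprocess' failed: {exc}") from exc

    try:
        report = run_study(config)
        for p in write_reports(report, outdir):
            manifest.add(p)
        manifest.stages.append("evaluate")
    except Exception as exc:
        raise RuntimeError(f"stage 'evaluate' failed: {exc}") from exc

    manifest.finished = time.time()
    manifest.write(outdir / "manifest.json")
    return manifest
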