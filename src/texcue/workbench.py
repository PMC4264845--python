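"""Tabular I/O, run configuration and the simulate -> fit -> analyze pipeline.

The canonical interchange format is a versioned CSV trial table with one row
per (observer, comparison, condition, contrast level):

    observer_id, comparison, condition, level_index, nontexture_contrast,
    texture_contrast, n_trials, k_chose_nontexture

The first line is the version comment ``# texcue-trials v1``.  Workbook
(.xlsx) ingestion is a thin converter for externally deposited data, with a
user-configurable column map because deposited sheet layouts vary.

Every randomised output is reproducible from (config, seed) alone, and all
file writes are atomic (write to a temp file, then rename), so interrupted
runs never leave truncated outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import tempfile
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._version import __version__
from .errors import TrialTableError
from .psychofit import LogisticFit, fit_ml, fit_with_se
from .shift_stats import ShiftSummary, summarize_comparison
from .stimulus import ContrastLadder, make_ladder
from .synthetic_observer import PsychometricDataset, simulate_cohort

__all__ = [
    "RunConfig",
    "TRIAL_COLUMNS",
    "atomic_write_text",
    "datasets_from_trials",
    "read_trials",
    "run_pipeline",
    "trials_from_cohort",
    "validate_trials",
    "write_trials",
]

log = logging.getLogger("texcue")

TRIAL_FORMAT_VERSION = "texcue-trials v1"
TRIAL_COLUMNS = [
    "observer_id",
    "comparison",
    "condition",
    "level_index",
    "nontexture_contrast",
    "texture_contrast",
    "n_trials",
    "k_chose_nontexture",
]


def atomic_write_text(path: str | os.PathLike, text: str) -> None:
    """Write text atomically: temp file in the same directory, then rename."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# ---------------------------------------------------------------------------
# Trial tables


def validate_trials(df: pd.DataFrame) -> pd.DataFrame:
    """Schema-check a trial table; raises TrialTableError naming bad rows."""
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise TrialTableError(f"trial table is missing columns: {missing}")
    df = df[TRIAL_COLUMNS].copy()
    bad_k = df.index[df["k_chose_nontexture"] > df["n_trials"]].tolist()
    if bad_k:
        raise TrialTableError(f"k > n at rows {bad_k}")
    bad_neg = df.index[
        (df["k_chose_nontexture"] < 0) | (df["n_trials"] < 1)
    ].tolist()
    if bad_neg:
        raise TrialTableError(f"negative counts or empty levels at rows {bad_neg}")
    bad_c = df.index[
        (df["nontexture_contrast"] <= 0) | (df["texture_contrast"] <= 0)
    ].tolist()
    if bad_c:
        raise TrialTableError(f"non-positive contrast at rows {bad_c}")

    for key, group in df.groupby(["observer_id", "comparison", "condition"]):
        if group["level_index"].duplicated().any():
            raise TrialTableError(f"duplicate level_index within session {key}")
        if len(group) != 8:
            warnings.warn(
                f"session {key} has {len(group)} levels (expected 8); "
                "proceeding with a reduced design",
                UserWarning,
                stacklevel=2,
            )
    return df


def trials_from_cohort(
    cohort: list[tuple[PsychometricDataset, PsychometricDataset]],
    ladder: ContrastLadder,
) -> pd.DataFrame:
    """Flatten a simulated cohort into the canonical trial-table rows."""
    rows = []
    pairs = ladder.pairs()
    for sep, comb in cohort:
        for ds in (sep, comb):
            for i in range(len(ds.x_levels)):
                a, b = pairs[i]
                rows.append(
                    {
                        "observer_id": ds.observer,
                        "comparison": ds.comparison,
                        "condition": ds.condition,
                        "level_index": i + 1,
                        "nontexture_contrast": a,
                        "texture_contrast": b,
                        "n_trials": int(ds.n_per_level[i]),
                        "k_chose_nontexture": int(ds.k_chose_nontexture[i]),
                    }
                )
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def datasets_from_trials(df: pd.DataFrame) -> list[PsychometricDataset]:
    """Group a trial table into per-session datasets, x = log10(a/b)."""
    df = validate_trials(df)
    out = []
    for (obs, comp, cond), g in df.groupby(
        ["observer_id", "comparison", "condition"], sort=True
    ):
        g = g.sort_values("level_index")
        out.append(
            PsychometricDataset(
                x_levels=np.log10(
                    g["nontexture_contrast"].to_numpy()
                    / g["texture_contrast"].to_numpy()
                ),
                n_per_level=g["n_trials"].to_numpy(),
                k_chose_nontexture=g["k_chose_nontexture"].to_numpy(),
                observer=str(obs),
                comparison=str(comp),
                condition=str(cond),
            )
        )
    return out


def write_trials(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write the canonical versioned CSV (atomic)."""
    df = validate_trials(df)
    text = f"# {TRIAL_FORMAT_VERSION}\n" + df.to_csv(
        index=False, float_format="%.17g"
    )
    atomic_write_text(path, text)


def read_trials(
    path: str | os.PathLike,
    fmt: str | None = None,
    column_map: dict[str, str] | None = None,
    sheet_comparisons: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Read a trial table from CSV or an Excel workbook.

    Parameters
    ----------
    fmt : {"csv", "xlsx"}, optional
        Inferred from the suffix when omitted.
    column_map : dict, optional
        Maps canonical column names to the file's column names, for
        externally deposited workbooks whose headers differ.
    sheet_comparisons : dict, optional
        For workbooks with one sheet per cue comparison and no comparison
        column: maps sheet name -> comparison label.
    """
    path = Path(path)
    if fmt is None:
        fmt = "xlsx" if path.suffix.lower() in (".xlsx", ".xls") else "csv"
    if fmt == "csv":
        frames = [pd.read_csv(path, comment="#")]
    elif fmt == "xlsx":
        sheets = pd.read_excel(path, sheet_name=None)
        frames = []
        for name, frame in sheets.items():
            if sheet_comparisons is not None:
                if name not in sheet_comparisons:
                    continue
                frame = frame.copy()
                frame["comparison"] = sheet_comparisons[name]
            frames.append(frame)
    else:
        raise ValueError(f"unknown trial-table format {fmt!r}")

    df = pd.concat(frames, ignore_index=True)
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    return validate_trials(df)


# ---------------------------------------------------------------------------
# Run configuration and pipeline


@dataclass(frozen=True)
class ComparisonConfig:
    """Generative truth and ladder bounds for one cue comparison."""

    mean_shift: float
    sd_shift: float
    a_min: float = 0.1
    a_max: float = 0.32
    b_min: float = 0.1
    b_max: float = 0.32

    def ladder(self, n_levels: int = 8) -> ContrastLadder:
        return make_ladder(self.a_min, self.a_max, self.b_min, self.b_max, n_levels)


def _default_comparisons() -> dict[str, ComparisonConfig]:
    # study conditions: reported mean shifts and SDs per comparison
    return {
        "Dark": ComparisonConfig(mean_shift=0.091, sd_shift=0.04),
        "Red": ComparisonConfig(mean_shift=0.079, sd_shift=0.034),
        "Violet": ComparisonConfig(mean_shift=0.06, sd_shift=0.05),
    }


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a synthetic study end to end."""

    seed: int = 0
    n_observers: int = 7
    n_per_level: int = 20
    n_levels: int = 8
    base_alpha: float = -0.1
    beta_separate: float = 10.0
    beta_combined: float = 10.0
    n_boot: int = 200
    comparisons: dict[str, ComparisonConfig] = field(
        default_factory=_default_comparisons
    )

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        comps = {
            name: ComparisonConfig(**cc)
            for name, cc in d.pop("comparisons", {}).items()
        } or _default_comparisons()
        return cls(comparisons=comps, **d)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def fit_cohort(
    cohort: list[tuple[PsychometricDataset, PsychometricDataset]],
    n_boot: int = 0,
    seed: int | np.random.SeedSequence | None = 0,
) -> tuple[list[LogisticFit], list[LogisticFit]]:
    """Fit every session of a cohort; bootstrap SEs when n_boot >= 100."""
    root = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    streams = iter(root.spawn(2 * len(cohort)))
    fits_sep, fits_comb = [], []
    for sep, comb in cohort:
        for ds, bucket in ((sep, fits_sep), (comb, fits_comb)):
            stream = next(streams)
            if n_boot >= 100:
                bucket.append(fit_with_se(ds, n_boot=n_boot, seed=stream))
            else:
                bucket.append(fit_ml(ds))
    return fits_sep, fits_comb


def run_pipeline(
    config: RunConfig, out_dir: str | os.PathLike
) -> dict[str, ShiftSummary]:
    """Simulate, fit and analyze one synthetic study; write all artefacts.

    Writes ``trials.csv``, ``fits.json`` and ``summaries.json`` under
    ``out_dir``; every output embeds the seed, config hash and software
    version.  Byte-identical outputs for identical (config, seed).
    """
    out_dir = Path(out_dir)
    root = np.random.SeedSequence(config.seed)
    provenance = {
        "seed": config.seed,
        "config_hash": config.config_hash,
        "version": __version__,
    }

    tables, fit_records, summaries = [], [], {}
    comp_streams = root.spawn(2 * len(config.comparisons))
    for idx, (comparison, cc) in enumerate(sorted(config.comparisons.items())):
        log.info("simulate: comparison=%s", comparison)
        ladder = cc.ladder(config.n_levels)
        cohort = simulate_cohort(
            n_observers=config.n_observers,
            mean_shift=cc.mean_shift,
            sd_shift=cc.sd_shift,
            base_alpha=config.base_alpha,
            betas=(config.beta_separate, config.beta_combined),
            ladder=ladder,
            seed=comp_streams[2 * idx],
            n_per_level=config.n_per_level,
            comparison=comparison,
        )
        tables.append(trials_from_cohort(cohort, ladder))

        log.info("fit: comparison=%s (%d sessions)", comparison, 2 * len(cohort))
        fits_sep, fits_comb = fit_cohort(
            cohort, n_boot=config.n_boot, seed=comp_streams[2 * idx + 1]
        )
        for cond, fits in (("Separate", fits_sep), ("Combined", fits_comb)):
            for (sep_ds, _), fit in zip(cohort, fits):
                fit_records.append(
                    {
                        "observer": sep_ds.observer,
                        "comparison": comparison,
                        "condition": cond,
                        **{
                            k: (None if isinstance(v, float) and np.isnan(v) else v)
                            for k, v in asdict(fit).items()
                        },
                    }
                )

        log.info("analyze: comparison=%s", comparison)
        summaries[comparison] = summarize_comparison(
            comparison, fits_sep, fits_comb
        )

    write_trials(pd.concat(tables, ignore_index=True), out_dir / "trials.csv")
    atomic_write_text(
        out_dir / "fits.json",
        json.dumps({**provenance, "fits": fit_records}, indent=2, sort_keys=True),
    )
    atomic_write_text(
        out_dir / "summaries.json",
        json.dumps(
            {
                **provenance,
                "summaries": {k: v.to_dict() for k, v in summaries.items()},
            },
            indent=2,
            sort_keys=True,
        ),
    )
    log.info("pipeline complete: %s", out_dir)
    return summaries
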