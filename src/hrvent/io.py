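"""Plain-text persistence: traces, datasets, HR logs, posterior draws.

All tables are UTF-8 CSV with "." as the decimal separator.  Posterior
draws are stored as a tidy long table (chain, iteration, parameter,
value) next to a JSON sidecar holding the sampler metadata (seed,
settings, split-R̂, divergence counts, HR support).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from hrvent.models import (
    COL_DOMAIN,
    COL_HR,
    COL_SUBJECT,
    COL_VE,
    ModelForm,
    PosteriorDraws,
)
from hrvent.segmentation import TRACE_COLUMNS, BreathTrace
from hrvent.field import HRLOG_COLUMNS, PREDICTION_COLUMNS, HrLog

DATASET_COLUMNS = [COL_SUBJECT, COL_HR, COL_DOMAIN, COL_VE]


def write_trace(trace: BreathTrace, path: str | Path) -> None:
    df = trace.samples[TRACE_COLUMNS].copy()
    df.insert(0, COL_SUBJECT, trace.subject_id)
    df.to_csv(path, index=False)


def read_trace(
    path: str | Path,
    body_mass_kg: float | None = None,
    age_yr: float | None = None,
    rpe_final: float | None = None,
) -> BreathTrace:
    df = pd.read_csv(path)
    subject = str(df[COL_SUBJECT].iloc[0]) if COL_SUBJECT in df.columns else Path(path).stem
    return BreathTrace(
        subject_id=subject,
        samples=df[TRACE_COLUMNS].reset_index(drop=True),
        body_mass_kg=body_mass_kg,
        age_yr=age_yr,
        rpe_final=rpe_final,
    )


def write_dataset(data: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in DATASET_COLUMNS if c in data.columns]
    data[cols].to_csv(path, index=False)


def read_dataset(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_hrlog(log: HrLog, path: str | Path) -> None:
    log.samples[HRLOG_COLUMNS].to_csv(path, index=False)


def read_hrlog(path: str | Path, **metadata) -> HrLog:
    return HrLog(samples=pd.read_csv(path)[HRLOG_COLUMNS], **metadata)


def write_predictions(pred: pd.DataFrame, path: str | Path) -> None:
    pred[PREDICTION_COLUMNS].to_csv(path, index=False)


def read_predictions(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# Posterior draws
# ---------------------------------------------------------------------------


def save_draws(draws: PosteriorDraws, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    params = draws.scalar_parameters()
    c, d = draws.n_chains, draws.n_draws
    chain_col = np.repeat(np.arange(c), d)
    iter_col = np.tile(np.arange(d), c)
    frames = [
        pd.DataFrame({
            "chain": chain_col,
            "iteration": iter_col,
            "parameter": name,
            "value": vals.reshape(-1),
        })
        for name, vals in params.items()
    ]
    pd.concat(frames, ignore_index=True).to_csv(directory / "draws.csv", index=False)
    meta = dict(draws.meta)
    meta.update(
        form=draws.form.value,
        subject_ids=[str(s) for s in draws.subject_ids],
        n_chains=c,
        n_draws=d,
        hierarchical=draws.hierarchical,
    )
    (directory / "meta.json").write_text(json.dumps(meta, indent=2))


def load_draws(directory: str | Path) -> PosteriorDraws:
    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text())
    long = pd.read_csv(directory / "draws.csv")
    c, d = int(meta["n_chains"]), int(meta["n_draws"])
    form = ModelForm.coerce(meta["form"])
    k = form.n_coef
    wide = {
        name: g.sort_values(["chain", "iteration"])["value"].to_numpy().reshape(c, d)
        for name, g in long.groupby("parameter", sort=False)
    }
    beta = np.stack([wide[f"beta{i}"] for i in range(k)], axis=-1)
    if meta.get("hierarchical", True):
        sigma_b = np.stack([wide[f"sigma_b{i}"] for i in range(k)], axis=-1)
        corr = np.zeros((c, d, k, k))
        corr[:, :, np.arange(k), np.arange(k)] = 1.0
        for i in range(k):
            for j in range(i + 1, k):
                corr[:, :, i, j] = corr[:, :, j, i] = wide[f"rho_b{i}_b{j}"]
        subject_ids = meta["subject_ids"]
        b = np.zeros((c, d, len(subject_ids), k))
        for jdx in range(len(subject_ids)):
            for i in range(k):
                b[:, :, jdx, i] = wide[f"b[{jdx},{i}]"]
    else:
        sigma_b = corr = b = None
        subject_ids = meta["subject_ids"]
    draws = PosteriorDraws(
        form=form,
        beta=beta,
        sigma_within=wide["sigma_within"],
        sigma_b=sigma_b,
        corr=corr,
        b=b,
        subject_ids=subject_ids,
    )
    draws.meta = {
        key: v
        for key, v in meta.items()
        if key not in {"form", "subject_ids", "n_chains", "n_draws", "hierarchical"}
    }
    return draws
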