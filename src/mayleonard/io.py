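"""Plain-text export formats: snapshots, spectra, sweep tables, manifests."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import SPECIES_LABELS
from .spectral import Spectrum


def write_snapshot(path, x, y, sp) -> None:
    """One row per individual: ``species,x,y`` with species in {A,B,C}."""
    labels = [SPECIES_LABELS[int(s)] for s in sp]
    pd.DataFrame({"species": labels, "x": np.asarray(x), "y": np.asarray(y)}
                 ).to_csv(path, index=False)


def read_snapshot(path):
    """Read a snapshot back as (x, y, species_index) arrays."""
    df = pd.read_csv(path)
    idx = {s: i for i, s in enumerate(SPECIES_LABELS)}
    sp = df["species"].map(idx)
    if sp.isna().any():
        bad = df.loc[sp.isna(), "species"].iloc[0]
        raise ValueError(f"unknown species label {bad!r} in snapshot")
    return (df["x"].to_numpy(), df["y"].to_numpy(), sp.to_numpy(dtype=np.int64))


def write_spectrum(path, spec: Spectrum) -> None:
    pd.DataFrame({"k": spec.frequencies, "power": spec.power,
                  "replicates": spec.replicates,
                  "NG": spec.n_components}).to_csv(path, index=False)


def read_spectrum(path) -> Spectrum:
    df = pd.read_csv(path)
    return Spectrum(frequencies=df["k"].to_numpy(),
                    power=df["power"].to_numpy(),
                    replicates=int(df["replicates"].iloc[0]),
                    n_components=int(df["NG"].iloc[0]))


def write_sweep(path, sweep: pd.DataFrame) -> None:
    sweep.to_csv(path, index=False,
                 columns=["M", "mean_N", "stderr_N", "replicates"])


def read_sweep(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_manifest(path, entries: dict) -> None:
    """Flat ``key = value`` run manifest, sufficient to re-run a scenario."""
    lines = [f"{k} = {v}" for k, v in entries.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_manifest(path) -> dict:
    out = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        key, _, val = line.partition("=")
        out[key.strip()] = val.strip()
    return out
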