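"""Reading and writing the on-disk formats.

Layout written by the simulator (and accepted by the pipeline)::

    DIR/
      metadata.json                  # bands, protocol, seed, true parameters
      <BAND>_trial<k>.tif            # 32-bit float multi-page TIFF per trial
      lfp_<rate>Hz.csv               # optional two-column LFP traces

Masks are single-page 8-bit TIFFs (nonzero = true); corrected stacks and OIS
maps are 32-bit float TIFFs; time courses and chromophores are plain CSV.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile

from .core import FrameStack, LFPTrace, OISMap, Protocol, ROIMask, TimeCourse, TrialSet
from .mbll import ChromophoreTimecourses

__all__ = [
    "write_trials",
    "read_trials",
    "write_stack",
    "read_stack",
    "write_mask",
    "read_mask",
    "write_map",
    "save_map_preview",
    "timecourse_to_csv",
    "timecourse_from_csv",
    "chromophores_to_csv",
    "lfp_to_csv",
    "lfp_from_csv",
]


def write_stack(path: str | Path, stack: FrameStack) -> None:
    tifffile.imwrite(str(path), stack.data.astype(np.float32))


def read_stack(path: str | Path, band: str, protocol: Protocol, mode: str = "reflectance") -> FrameStack:
    data = tifffile.imread(str(path)).astype(float)
    return FrameStack(data=data, band=band, protocol=protocol, mode=mode)


def write_trials(
    out_dir: str | Path,
    trial_sets: Mapping[str, TrialSet],
    protocol: Protocol,
    mode: str = "reflectance",
    seed: int | None = None,
    true_params: Mapping | None = None,
) -> Path:
    """Write per-band per-trial TIFF stacks plus the JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for band, ts in trial_sets.items():
        for k, tr in enumerate(ts.trials):
            write_stack(out / f"{band}_trial{k:03d}.tif", tr)
    meta = {
        "bands": list(trial_sets),
        "n_trials": {band: ts.n_trials for band, ts in trial_sets.items()},
        "mode": mode,
        "protocol": protocol.to_dict(),
        "seed": seed,
        "true_params": dict(true_params) if true_params else None,
    }
    (out / "metadata.json").write_text(json.dumps(meta, indent=2) + "\n")
    return out


def read_trials(in_dir: str | Path) -> tuple[dict[str, TrialSet], dict]:
    """Read the TIFF + sidecar layout back into per-band trial sets."""
    in_dir = Path(in_dir)
    meta = json.loads((in_dir / "metadata.json").read_text())
    protocol = Protocol.from_dict(meta["protocol"])
    mode = meta.get("mode", "reflectance")
    sets: dict[str, TrialSet] = {}
    for band in meta["bands"]:
        paths = sorted(in_dir.glob(f"{band}_trial*.tif"))
        if not paths:
            raise FileNotFoundError(f"no trial stacks for band {band!r} in {in_dir}")
        sets[band] = TrialSet(
            trials=[read_stack(p, band=band, protocol=protocol, mode=mode) for p in paths]
        )
    return sets, meta


def write_mask(path: str | Path, mask: ROIMask) -> None:
    tifffile.imwrite(str(path), (mask.mask.astype(np.uint8) * 255))


def read_mask(path: str | Path, role: str) -> ROIMask:
    return ROIMask(mask=tifffile.imread(str(path)) != 0, role=role)  # type: ignore[arg-type]


def write_map(path: str | Path, ois_map: OISMap) -> None:
    tifffile.imwrite(str(path), ois_map.values.astype(np.float32))


def save_map_preview(path: str | Path, ois_map: OISMap) -> None:
    """PNG preview with a symmetric diverging scale around zero."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    v = float(np.max(np.abs(ois_map.values))) or 1.0
    fig, ax = plt.subplots(figsize=(4, 3))
    im = ax.imshow(ois_map.values * 100, cmap="RdBu_r", vmin=-100 * v, vmax=100 * v)
    fig.colorbar(im, ax=ax, label="OIS (%)")
    ax.set_title(f"{ois_map.band} ({ois_map.mode})")
    fig.tight_layout()
    fig.savefig(str(path), dpi=120)
    plt.close(fig)


def timecourse_to_csv(path: str | Path, tc: TimeCourse) -> None:
    df = pd.DataFrame(
        {"time_s": tc.t, "signal_frac": tc.y, "signal_percent": tc.y * 100.0}
    )
    header = (
        f"# band: {tc.band}\n# mode: {tc.mode}\n# polarity: {tc.polarity}\n"
        f"# stim_onset_s: {tc.stim_onset_s}\n"
    )
    Path(path).write_text(header + df.to_csv(index=False))


def timecourse_from_csv(path: str | Path) -> TimeCourse:
    meta: dict[str, str] = {}
    lines = Path(path).read_text().splitlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = val.strip()
            body_start = i + 1
        else:
            break
    from io import StringIO

    df = pd.read_csv(StringIO("\n".join(lines[body_start:])))
    return TimeCourse(
        t=df["time_s"].to_numpy(),
        y=df["signal_frac"].to_numpy(),
        stim_onset_s=float(meta.get("stim_onset_s", 0.0)),
        mode=meta.get("mode", "reflectance"),  # type: ignore[arg-type]
        polarity=meta.get("polarity", "activation-positive"),  # type: ignore[arg-type]
        band=meta.get("band", ""),
    )


def chromophores_to_csv(path: str | Path, c: ChromophoreTimecourses) -> None:
    pd.DataFrame(
        {
            "time_s": c.t,
            "dHbO_uM": c.d_hbo,
            "dHbR_uM": c.d_hbr,
            "dS": c.d_s,
            "HbT_uM": c.hbt,
        }
    ).to_csv(path, index=False)


def lfp_to_csv(path: str | Path, lfp: LFPTrace) -> None:
    pd.DataFrame({"time_s": lfp.t, "microvolts": lfp.v}).to_csv(path, index=False)


def lfp_from_csv(path: str | Path, stim_onset_s: float = 5.0, stim_rate_hz: float = 1.0) -> LFPTrace:
    df = pd.read_csv(path)
    return LFPTrace(
        t=df["time_s"].to_numpy(),
        v=df["microvolts"].to_numpy(),
        stim_onset_s=stim_onset_s,
        stim_rate_hz=stim_rate_hz,
    )
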