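"""Readers and writers for on-disk FLIM data and fit results.

Image stacks travel as multi-frame TIFFs (one frame per gate or time
bin; polarisation channels stacked channel-major, parallel channel
first) with a plain ``key=value`` sidecar describing the time axis.
Results are written as delimited text: a global parameter table, a
per-region statistics CSV and per-pixel parameter maps as
floating-point TIFFs.  Vendor TCSPC binary formats are out of scope;
this open container is the interchange format.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile

from .acquisition import AcquisitionScheme, parse_config
from .varpro import PixelDataset

__all__ = [
    "write_stack",
    "read_gated_stack",
    "read_tcspc_stack",
    "write_results",
]


def write_stack(
    path: str | Path,
    stack: np.ndarray,
    scheme: AcquisitionScheme,
    sidecar: str | Path | None = None,
) -> None:
    """Write an image stack (n_points, H, W) plus its sidecar config."""
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[0] != scheme.n_points:
        raise ValueError(
            f"stack must be (n_points={scheme.n_points}, H, W); got {stack.shape}"
        )
    tifffile.imwrite(str(path), stack.astype(np.float32), photometric="minisblack")
    sidecar = Path(sidecar) if sidecar else Path(path).with_suffix(".cfg")
    scheme.to_config(sidecar)


def _read_dataset(
    path: str | Path,
    sidecar: str | Path | None,
    expect_mode: str,
    intensity_threshold: float | None,
) -> tuple[PixelDataset, AcquisitionScheme]:
    sidecar = Path(sidecar) if sidecar else Path(path).with_suffix(".cfg")
    kv = parse_config(sidecar)
    if "rep_period" not in kv:
        raise ValueError(
            "sidecar lacks rep_period; the incomplete-decay correction needs it"
        )
    scheme = AcquisitionScheme.from_config(sidecar)
    if scheme.mode != expect_mode:
        raise ValueError(f"expected {expect_mode} data, sidecar says {scheme.mode}")
    stack = np.asarray(tifffile.imread(str(path)), dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.shape[0] != scheme.n_points:
        raise ValueError(
            f"stack has {stack.shape[0]} frames but the scheme defines "
            f"{scheme.n_points} (gates/bins x channels)"
        )
    dataset = PixelDataset.from_stack(
        stack, scheme.n_channels, intensity_threshold=intensity_threshold
    )
    return dataset, scheme


def read_gated_stack(
    path: str | Path,
    sidecar: str | Path | None = None,
    intensity_threshold: float | None = None,
) -> tuple[PixelDataset, AcquisitionScheme]:
    """Read a time-gated stack: one frame per gate, sidecar gives gate
    times/widths and the repetition period."""
    return _read_dataset(path, sidecar, "gated", intensity_threshold)


def read_tcspc_stack(
    path: str | Path,
    sidecar: str | Path | None = None,
    intensity_threshold: float | None = None,
) -> tuple[PixelDataset, AcquisitionScheme]:
    """Read a TCSPC stack: one frame per (channel, bin), channel-major."""
    return _read_dataset(path, sidecar, "tcspc", intensity_threshold)


def write_results(results, outdir: str | Path, confidence: float | None = None) -> None:
    """Write a fit's outputs: global parameter table (with optional
    support-plane confidence bounds), per-region statistics CSV, and one
    floating-point TIFF map per per-pixel quantity."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if confidence is not None:
        table = results.conf_int(confidence)[["estimate", "lower", "upper"]]
    else:
        import pandas as pd

        table = pd.DataFrame({"estimate": results.params})
    table.to_csv(outdir / "global_parameters.csv")
    results.region_statistics().to_csv(outdir / "region_statistics.csv")

    if results.model.dataset.image_shape is not None:
        import pandas as pd

        maps = pd.concat([results.linear_params, results.derived], axis=1)
        for name in maps.columns:
            safe = name.replace("(", "_").replace(")", "").replace("/", "_")
            tifffile.imwrite(
                str(outdir / f"map_{safe}.tif"),
                results.parameter_map(name).astype(np.float32),
                photometric="minisblack",
            )
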