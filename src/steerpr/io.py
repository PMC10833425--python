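"""HDF5 run containers and image export.

One container per run holds everything: phantom, pattern, trial states,
steering logs and analysis products, so provenance never splits across
files.  Layout:

    /phantom/values                  ground-truth density (synthetic runs)
    /pattern/amplitude               measured |F|, zero-frequency centered
    /pattern/valid                   boolean validity mask
    /trials/trial_{k}/final_map
    /trials/trial_{k}/support
    /trials/trial_{k}/cycle_{c}      snapshot maps
    /steering/stage_{s}/{histogram_counts,histogram_edges}
    /steering/stage_{s} attrs        cycle, w, reference, n_qualifying, min_T
    /analysis/{plane,projections,labels,frequency}
    /log                             structured text log of barrier events

Every group of outputs embeds the JSON-serialized configuration and the
seeds that produced it, so re-running ``analyze`` on a container needs no
external state.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from typing import Optional, Sequence

import h5py
import numpy as np

from .datatypes import (
    DensityMap,
    DiffractionPattern,
    PhasingConfig,
    SteeringConfig,
)
from .ensemble import EnsembleRecord

__all__ = [
    "write_pattern",
    "read_pattern",
    "write_phantom",
    "read_phantom",
    "write_run",
    "read_run_scores",
    "validate_run",
    "export_log_intensity_png",
]


class FormatError(ValueError):
    """A container violates the documented layout."""


def write_pattern(
    path, pattern: DiffractionPattern, attrs: Optional[dict] = None, mode="a"
) -> None:
    with h5py.File(path, mode) as f:
        grp = f.require_group("pattern")
        for name in ("amplitude", "valid"):
            if name in grp:
                del grp[name]
        grp.create_dataset("amplitude", data=pattern.amplitude)
        grp.create_dataset("valid", data=pattern.valid)
        grp.attrs["centering"] = "zero-frequency at (m/2, m/2)"
        for k, v in (attrs or {}).items():
            grp.attrs[k] = v


def read_pattern(path) -> DiffractionPattern:
    """Read and validate a diffraction pattern from a container."""
    with h5py.File(path, "r") as f:
        if "pattern" not in f:
            raise FormatError("container has no /pattern group")
        grp = f["pattern"]
        for name in ("amplitude", "valid"):
            if name not in grp:
                raise FormatError(f"missing dataset /pattern/{name}")
        amplitude = np.asarray(grp["amplitude"], dtype=float)
        valid = np.asarray(grp["valid"], dtype=bool)
    if amplitude.shape != valid.shape:
        raise FormatError(
            f"/pattern/amplitude shape {amplitude.shape} does not match "
            f"/pattern/valid shape {valid.shape}"
        )
    neg = np.argwhere((amplitude < 0) & valid)
    if len(neg):
        r, c = neg[0]
        raise FormatError(
            f"/pattern/amplitude has a negative entry at pixel ({r}, {c})"
        )
    return DiffractionPattern(amplitude, valid)


def write_phantom(path, phantom: DensityMap, mode="a") -> None:
    with h5py.File(path, mode) as f:
        grp = f.require_group("phantom")
        if "values" in grp:
            del grp["values"]
        grp.create_dataset("values", data=phantom.values)
        if phantom.pixel_size is not None:
            grp.attrs["pixel_size_nm"] = phantom.pixel_size


def read_phantom(path) -> Optional[DensityMap]:
    with h5py.File(path, "r") as f:
        if "phantom" not in f or "values" not in f["phantom"]:
            return None
        values = np.asarray(f["phantom/values"], dtype=float)
        pixel = f["phantom"].attrs.get("pixel_size_nm")
    return DensityMap(values, pixel_size=pixel)


def write_run(
    path,
    record: EnsembleRecord,
    phasing_config: Optional[PhasingConfig] = None,
    steering_config: Optional[SteeringConfig] = None,
    log_lines: Sequence[str] = (),
    mode="a",
) -> None:
    """Append an ensemble record (trials + steering logs) to a container."""
    with h5py.File(path, mode) as f:
        if "trials" in f:
            del f["trials"]
        if "steering" in f:
            del f["steering"]
        trials = f.create_group("trials")
        trials.attrs["mode"] = record.mode
        trials.attrs["seeds"] = np.asarray(record.seeds)
        trials.attrs["converged"] = record.converged
        trials.attrs["terminated_early"] = record.terminated_early
        if record.trigger_cycle is not None:
            trials.attrs["trigger_cycle"] = record.trigger_cycle
        config = {}
        if phasing_config is not None:
            config["phasing"] = asdict(phasing_config)
        if steering_config is not None:
            config["steering"] = asdict(steering_config)
        trials.attrs["config_json"] = json.dumps(config, sort_keys=True)
        for k, t in enumerate(record.trials):
            grp = trials.create_group(f"trial_{k}")
            grp.create_dataset("final_map", data=t.final_map)
            grp.create_dataset("support", data=t.final_support)
            grp.attrs["cycle"] = t.cycle
            grp.attrs["zeta"] = t.zeta
            grp.attrs["zeta_latched"] = t.zeta_latched
            grp.attrs["failed"] = t.failed
            grp.attrs["seed"] = t.seed
            for c, snap in t.snapshots.items():
                grp.create_dataset(f"cycle_{c}", data=snap)
        steering = f.create_group("steering")
        for s, (counts, edges) in record.histograms.items():
            grp = steering.create_group(f"stage_{s}")
            grp.create_dataset("histogram_counts", data=counts)
            grp.create_dataset("histogram_edges", data=edges)
        for entry in record.modification_log:
            grp = steering[f"stage_{entry['stage']}"]
            for key, value in entry.items():
                grp.attrs[key] = value
        if log_lines:
            if "log" in f:
                del f["log"]
            f.create_dataset(
                "log", data=np.array(list(log_lines), dtype=h5py.string_dtype())
            )


def read_run_scores(path) -> dict:
    """Re-read the per-stage score histograms from a container."""
    out = {}
    with h5py.File(path, "r") as f:
        if "steering" not in f:
            return out
        for name, grp in f["steering"].items():
            stage = int(name.split("_")[1])
            out[stage] = (
                np.asarray(grp["histogram_counts"]),
                np.asarray(grp["histogram_edges"]),
            )
    return out


def validate_run(path) -> None:
    """Schema check: raise :class:`FormatError` on a malformed container."""
    with h5py.File(path, "r") as f:
        if "trials" not in f:
            raise FormatError("container has no /trials group")
        trials = [k for k in f["trials"] if k.startswith("trial_")]
        if not trials:
            raise FormatError("/trials holds no trial groups")
        for k in trials:
            grp = f["trials"][k]
            for name in ("final_map", "support"):
                if name not in grp:
                    raise FormatError(f"missing dataset /trials/{k}/{name}")
            if grp["final_map"].shape != grp["support"].shape:
                raise FormatError(f"/trials/{k}: map and support shapes differ")
        if "steering" in f:
            for name, grp in f["steering"].items():
                for ds in ("histogram_counts", "histogram_edges"):
                    if ds not in grp:
                        raise FormatError(
                            f"missing dataset /steering/{name}/{ds}"
                        )


def write_analysis(path, plane, projections, labels, frequency) -> None:
    with h5py.File(path, "a") as f:
        if "analysis" in f:
            del f["analysis"]
        grp = f.create_group("analysis")
        grp.create_dataset("plane", data=plane.components)
        grp.create_dataset("explained_variance", data=plane.explained_variance)
        grp.create_dataset("projections", data=projections)
        grp.create_dataset("labels", data=labels)
        grp.create_dataset("frequency", data=frequency)


def export_log_intensity_png(path, pattern: DiffractionPattern) -> None:
    """Save the pattern as a grayscale log-intensity image (invalid black)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    img = np.log10(1.0 + pattern.intensity)
    img = np.where(pattern.valid, img, 0.0)
    plt.imsave(path, img, cmap="gray")
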