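"""Output artifacts: HDF5 state dumps, tidy CSV traces, JSON summaries."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .observables import occupancy_trace, traces_frame
from .solver import Trajectory, conservation_report


def write_trajectory_h5(traj: Trajectory, path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as h5:
        h5.attrs["photon_keV"] = traj.pulse.photon_kev
        h5.attrs["fluence_per_um2"] = traj.pulse.fluence_per_um2
        h5.attrs["shape"] = traj.pulse.shape
        h5.attrs["fwhm_fs"] = traj.pulse.fwhm_fs
        h5.create_dataset("basis/breakpoints", data=traj.basis.breakpoints)
        h5.attrs["basis_order"] = traj.basis.order
        h5.create_dataset("times_fs", data=traj.times)
        h5.create_dataset("coefficients",
                          data=np.vstack([s.coef for s in traj.samples]))
        for name in traj.samples[0].ledgers:
            h5.create_dataset(
                f"ledgers/{name}",
                data=np.array([s.ledgers[name] for s in traj.samples]))
        for sym in traj.element_symbols:
            g = h5.create_group(f"elements/{sym}")
            g.attrs["density_cm3"] = traj.densities[sym]
            g.attrs["shells"] = ",".join(traj.shell_labels[sym])
            g.create_dataset("charge", data=traj.charge_trace(sym))
            g.create_dataset("shell_occ", data=np.vstack(
                [s.shell_occ[sym] for s in traj.samples]))
            idx = sorted({i for s in traj.samples
                          for i in s.populations[sym]})
            g.create_dataset("config_index", data=np.array(idx, dtype=np.int64))
            P = np.zeros((len(traj.samples), len(idx)))
            lut = {i: k for k, i in enumerate(idx)}
            for r, s in enumerate(traj.samples):
                for i, p in s.populations[sym].items():
                    P[r, lut[i]] = p
            g.create_dataset("populations", data=P)
    return path


def write_element_tables_h5(model, path, config_indices=None) -> Path:
    """Serialize an ElementModel's computed tables (configuration index
    map, binding/kinetic energies, decay rates) to HDF5, with all
    computed configurations by default."""
    path = Path(path)
    idxs = sorted(config_indices or model._data)
    with h5py.File(path, "w") as h5:
        h5.attrs["Z"] = model.Z
        h5.attrs["collapse_threshold"] = model.collapse_threshold
        h5.attrs["shells"] = ",".join(s.label for s in model.shells)
        occ = np.array([model.configs.occ_of(i) for i in idxs])
        h5.create_dataset("config_index", data=np.array(idxs, dtype=np.int64))
        h5.create_dataset("occupancies", data=occ)
        h5.create_dataset("total_energy_eV", data=np.array(
            [model.config_data(i).total_energy_ev for i in idxs]))
        h5.create_dataset("binding_eV", data=np.vstack(
            [model.config_data(i).shell_binding_ev for i in idxs]))
        h5.create_dataset("kinetic_eV", data=np.vstack(
            [model.config_data(i).shell_kinetic_ev for i in idxs]))
    return path


def dump_element_tables_tsv(model, path, config_indices=None) -> Path:
    """Human-readable TSV dump of computed per-configuration data."""
    path = Path(path)
    idxs = sorted(config_indices or model._data)
    labels = [s.label for s in model.shells]
    with open(path, "w") as fh:
        fh.write("index\tocc\tE_total_eV\t"
                 + "\t".join(f"B({l})_eV" for l in labels) + "\n")
        for i in idxs:
            cd = model.config_data(i)
            occ = "".join(str(o) for o in cd.occ)
            bs = "\t".join(f"{b:.2f}" for b in cd.shell_binding_ev)
            fh.write(f"{i}\t{occ}\t{cd.total_energy_ev:.3f}\t{bs}\n")
    return path


def write_outputs(traj: Trajectory, out_dir) -> dict:
    """Standard artifact set: HDF5 + CSV traces + JSON summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h5path = write_trajectory_h5(traj, out / "trajectory.h5")
    traces = traces_frame(traj)
    traces.to_csv(out / "charge_traces.csv", index=False,
                  float_format="%.8g")
    occ_frames = [occupancy_trace(traj, s) for s in traj.element_symbols]
    import pandas as pd
    pd.concat(occ_frames).to_csv(out / "occupancies.csv", index=False,
                                 float_format="%.8g")
    rep = conservation_report(traj)
    summary = {
        "pulse": {"photon_keV": traj.pulse.photon_kev,
                  "fluence_per_um2": traj.pulse.fluence_per_um2,
                  "shape": traj.pulse.shape,
                  "fwhm_fs": traj.pulse.fwhm_fs},
        "window_fs": [float(traj.times[0]), float(traj.times[-1])],
        "final_charges": {s: float(traj.charge_trace(s)[-1])
                          for s in traj.element_symbols},
        "final_free_density_cm3": traj.samples[-1].free_density,
        "max_electron_drift": rep["max_electron_drift"],
        "max_energy_residual": rep["max_energy_residual"],
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2,
                                                 sort_keys=True))
    return {"h5": h5path, "csv": out / "charge_traces.csv",
            "summary": out / "summary.json"}
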