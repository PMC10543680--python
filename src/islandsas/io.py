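"""Curve and configuration I/O.

Scattering curves are whitespace-delimited 2-3 column text files
(q [1/A], intensity, optional uncertainty) with ``#`` comment lines.
System descriptions are single declarative YAML files; unknown keys are
rejected by name rather than silently ignored, and a config emitted by the
package re-parses to an identical system.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from .intensity import MembraneSystem, ScatteringCurve
from .profiles import ProbeContrast, SLDLevelProfile
from .structure import ParacrystalLattice2D, StackModel
from .systems import (
    DOPC,
    DPPC,
    PROTEINS,
    LipidSpecies,
    ProteinParams,
    build_domain_system,
    build_peripheral_protein,
    build_pore,
    build_transmembrane_protein,
    protein_concentration,
)

__all__ = [
    "read_curve",
    "write_curve",
    "q_from_inverse_nm",
    "load_config",
    "resolve_config",
    "system_from_config",
    "ConfigError",
]


def q_from_inverse_nm(q_nm: float | np.ndarray) -> np.ndarray:
    """Convert momentum transfer from 1/nm to 1/A (the unit used throughout)."""
    return np.asarray(q_nm, dtype=float) / 10.0


def read_curve(path: str | Path, probe: ProbeContrast | None = None,
               label: str = "") -> ScatteringCurve:
    """Read a 2-3 column text curve; comments are preserved in metadata.

    q is forced ascending (sorted with a warning comment); parse errors name
    the offending line.
    """
    path = Path(path)
    comments: list[str] = []
    rows: list[tuple[float, ...]] = []
    ncols = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                comments.append(line.lstrip("# ").rstrip())
                continue
            parts = line.split()
            if len(parts) not in (2, 3):
                raise ValueError(
                    f"{path}:{lineno}: expected 2 or 3 columns, got {len(parts)}"
                )
            try:
                vals = tuple(float(p) for p in parts)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric value ({exc})") from None
            if vals[0] <= 0:
                raise ValueError(f"{path}:{lineno}: non-positive q value {vals[0]}")
            if ncols is None:
                ncols = len(vals)
            elif len(vals) != ncols:
                raise ValueError(f"{path}:{lineno}: inconsistent column count")
            rows.append(vals)
    if not rows:
        raise ValueError(f"{path}: no data rows found")
    data = np.array(rows)
    order = np.argsort(data[:, 0])
    if not np.array_equal(order, np.arange(len(rows))):
        comments.append("q column was not ascending; rows sorted on read")
        data = data[order]
    sigma = data[:, 2] if ncols == 3 else None
    return ScatteringCurve(
        data[:, 0], data[:, 1], sigma, probe, label or path.stem, tuple(comments)
    )


def write_curve(curve: ScatteringCurve, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if curve.label:
            fh.write(f"# {curve.label}\n")
        if curve.probe is not None:
            fh.write(f"# probe: {curve.probe.kind} x_d={curve.probe.x_d}\n")
        for c in curve.comments:
            fh.write(f"# {c}\n")
        fh.write("# q[1/A]  intensity  sigma\n" if curve.sigma is not None
                 else "# q[1/A]  intensity\n")
        for i in range(len(curve)):
            if curve.sigma is not None:
                fh.write(
                    f"{curve.q[i]:.8e} {curve.intensity[i]:.8e} {curve.sigma[i]:.8e}\n"
                )
            else:
                fh.write(f"{curve.q[i]:.8e} {curve.intensity[i]:.8e}\n")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

class ConfigError(ValueError):
    pass


_LIPIDS = {"dppc": DPPC, "dopc": DOPC}

_SCHEMA = {
    "system": {
        "host_lipid": None,
        "concentration_mM": None,
        "island": {
            "type": None, "guest_lipid": None, "r1": None, "r_w": None,
            "protein": None, "embed": None, "xi": None,
        },
        "lattice": {"a": None, "g_a": None},
        "stack": {
            "n_bilayers": None, "c": None, "theory": None,
            "eta1": None, "g_cperp": None, "poly_width": None,
        },
    },
    "probe": {"kind": None, "x_d": None},
    "instrument": {"kappa": None, "background": None},
    "qgrid": {"qmin": None, "qmax": None, "n": None},
    "noise": {"rel_at_max": None, "eps": None},
    "seed": None,
    "label": None,
}

_LIPID_KEYS = {"name", "area", "volume", "thicknesses", "rho_x", "rho_n", "sigmas"}
_PROTEIN_KEYS = {
    "name", "mw", "volume", "radius", "delta", "phi_i", "phi_e",
    "length", "rho_x", "rho_n",
}


def _check_keys(cfg: dict, schema: dict, prefix: str = "") -> list[str]:
    unknown = []
    for key, val in cfg.items():
        if key not in schema:
            unknown.append(f"{prefix}{key}")
        elif isinstance(schema[key], dict) and isinstance(val, dict):
            if key == "island":
                unknown.extend(
                    f"{prefix}island.{k}" for k in val if k not in schema["island"]
                )
            else:
                unknown.extend(_check_keys(val, schema[key], f"{prefix}{key}."))
    return unknown


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    unknown = _check_keys(cfg, _SCHEMA)
    # lipid / protein sub-dicts are validated separately
    host = cfg.get("system", {}).get("host_lipid")
    if isinstance(host, dict):
        unknown.extend(
            f"system.host_lipid.{k}" for k in host if k not in _LIPID_KEYS
        )
    island = cfg.get("system", {}).get("island") or {}
    for sub, keys in (("guest_lipid", _LIPID_KEYS), ("protein", _PROTEIN_KEYS)):
        val = island.get(sub)
        if isinstance(val, dict):
            unknown.extend(f"system.island.{sub}.{k}" for k in val if k not in keys)
    if unknown:
        raise ConfigError("unknown config keys: " + ", ".join(sorted(unknown)))


def _lipid_from(value) -> LipidSpecies:
    if isinstance(value, str):
        try:
            return _LIPIDS[value.lower()]
        except KeyError:
            raise ConfigError(f"unknown lipid {value!r}") from None
    return LipidSpecies(
        name=value["name"], area=value["area"], volume=value["volume"],
        thicknesses=tuple(value["thicknesses"]), rho_x=tuple(value["rho_x"]),
        rho_n=tuple(value["rho_n"]), sigmas=tuple(value["sigmas"]),
    )


def _protein_from(value) -> ProteinParams:
    if isinstance(value, str):
        try:
            return PROTEINS[value.lower()]
        except KeyError:
            raise ConfigError(f"unknown protein {value!r}") from None
    return ProteinParams(**value)


def _probe_from(cfg: dict) -> ProbeContrast:
    p = cfg.get("probe", {}) or {}
    return ProbeContrast(p.get("kind", "xray"), p.get("x_d", 0.0))


def _stack_from(cfg: dict) -> StackModel:
    s = cfg.get("system", {}).get("stack") or {}
    return StackModel(
        n_bilayers=s.get("n_bilayers", 1), c=s.get("c", 65.0),
        theory=s.get("theory", "PT"), eta1=s.get("eta1"),
        g_cperp=s.get("g_cperp"), poly_width=s.get("poly_width", 0.3),
    )


def system_from_config(cfg: dict) -> MembraneSystem:
    """Build a MembraneSystem from a validated config mapping."""
    validate_config(cfg)
    sys_cfg = cfg.get("system", {})
    host = _lipid_from(sys_cfg.get("host_lipid", "dppc"))
    probe = _probe_from(cfg)
    stack = _stack_from(cfg)
    c_host = float(sys_cfg.get("concentration_mM", 3.0))
    island_cfg = sys_cfg.get("island")
    if not island_cfg:
        return MembraneSystem(
            bilayer=host.bilayer_profile(probe), probe=probe, stack=stack,
            concentrations=((c_host, host.volume),),
        )
    lat_cfg = sys_cfg.get("lattice") or {}
    if "a" not in lat_cfg:
        raise ConfigError("an island system requires system.lattice.a")
    lattice = ParacrystalLattice2D(a=float(lat_cfg["a"]),
                                   g_a=float(lat_cfg.get("g_a", 0.3)))
    kind = island_cfg.get("type")
    bilayer = host.bilayer_profile(probe)
    if kind == "domain":
        guest = _lipid_from(island_cfg.get("guest_lipid", "dopc"))
        return build_domain_system(
            host, guest, lattice.a, float(island_cfg["r1"]), lattice.g_a,
            c_host, probe, stack,
        )
    if kind == "pore":
        island = build_pore(float(island_cfg["r_w"]), bilayer)
        concs = ((c_host, host.volume),)
    elif kind == "transmembrane_protein":
        prot = _protein_from(island_cfg["protein"])
        island = build_transmembrane_protein(
            prot.radius, prot.delta, prot.phi_i, prot.phi_e, prot.length,
            prot.sld(probe), bilayer, embed=island_cfg.get("embed", "full"),
        )
        c_p = protein_concentration(c_host, lattice.a, prot.footprint, xi=1.0)
        concs = ((c_host, host.volume), (c_p, prot.volume))
    elif kind == "peripheral_protein":
        prot = _protein_from(island_cfg["protein"])
        xi = float(island_cfg.get("xi", 0.0))
        island = build_peripheral_protein(prot, xi, bilayer, probe)
        c_p = protein_concentration(c_host, lattice.a, prot.footprint, xi=xi)
        concs = ((c_host, host.volume), (c_p, prot.volume))
    else:
        raise ConfigError(f"unknown island type {kind!r}")
    return MembraneSystem(
        bilayer=bilayer, probe=probe, stack=stack, island=island,
        lattice=lattice, concentrations=concs,
    )


def resolve_config(cfg: dict) -> dict:
    """Normalise a config: named lipids/proteins are inlined so the emitted
    description is self-contained and round-trips to an identical system."""
    validate_config(cfg)
    out = yaml.safe_load(yaml.safe_dump(cfg))  # deep copy of plain types
    sys_cfg = out.setdefault("system", {})
    host = _lipid_from(sys_cfg.get("host_lipid", "dppc"))
    sys_cfg["host_lipid"] = _lipid_dict(host)
    island = sys_cfg.get("island")
    if island:
        if "guest_lipid" in island:
            island["guest_lipid"] = _lipid_dict(_lipid_from(island["guest_lipid"]))
        if "protein" in island:
            island["protein"] = asdict(_protein_from(island["protein"]))
    return out


def _lipid_dict(lipid: LipidSpecies) -> dict:
    d = asdict(lipid)
    for key in ("thicknesses", "rho_x", "rho_n", "sigmas"):
        d[key] = list(d[key])
    return d
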