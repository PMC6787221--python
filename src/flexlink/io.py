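"""Readers and writers for the pipeline's tabular and structural formats.

Formats: 3-column ``q I sigma`` text for SAXS curves ('#' comments),
TSV for shift and intensity tables (concentration headers in comment
lines), PDB with one Cα per residue for bead models, YAML for
configuration, and a JSON run manifest recording config, seed and input
digests so reruns are reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, is_dataclass
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
import yaml

from .datatypes import BeadModel, FormatError, IntensityTable, SAXSProfile, ShiftTable

log = logging.getLogger(__name__)

_FMT = "%.8g"  # preserves >= 6 significant digits on round trip


# ------------------------------------------------------------------ SAXS

def read_saxs_dat(path: str | Path) -> SAXSProfile:
    """Read a 3-column q/I/σ text file (q in Å⁻¹).

    Comment lines start with '#'.  Rows with non-positive q or σ are
    dropped with a logged count; fewer than 8 surviving rows is a format
    error.
    """
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise IOError(f"cannot read {path}: {exc}") from exc
    rows = []
    n_bad = 0
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 3:
            continue
        try:
            q, I, s = float(parts[0]), float(parts[1]), float(parts[2])
        except ValueError:
            continue
        if q <= 0 or s <= 0:
            n_bad += 1
            continue
        rows.append((q, I, s))
    if n_bad:
        log.warning("%s: dropped %d row(s) with non-positive q or sigma", path.name, n_bad)
    if len(rows) < 8:
        raise FormatError(f"{path}: only {len(rows)} valid rows (need >= 8)")
    arr = np.array(rows)
    order = np.argsort(arr[:, 0])
    return SAXSProfile(arr[order, 0], arr[order, 1], arr[order, 2], label=path.stem)


def write_saxs_dat(p: SAXSProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {p.label}\n# q(1/A)  I(a.u.)  sigma\n")
        for q, I, s in zip(p.q, p.I, p.sigma):
            fh.write(f"{_FMT % q}\t{_FMT % I}\t{_FMT % s}\n")


# ------------------------------------------------------------- titration

def read_titration_table(path: str | Path) -> ShiftTable:
    """Read a titration shift TSV.

    Layout::

        # P0_uM: 100 100 ...
        # L0_uM: 0 25 ...
        residue  domain  H0  N0  H1  N1  ...

    Missing peaks are written as ``NA`` and flagged (broadened), not
    dropped.  A missing L0 = 0 reference point or a duplicated residue id
    is a format error.
    """
    path = Path(path)
    P0 = L0 = None
    header = None
    rows = []
    for line in path.read_text().splitlines():
        if line.startswith("#"):
            if "P0_uM:" in line:
                P0 = [float(x) for x in line.split(":", 1)[1].split()]
            elif "L0_uM:" in line:
                L0 = [float(x) for x in line.split(":", 1)[1].split()]
            continue
        if not line.strip():
            continue
        if header is None:
            header = line.split("\t")
            continue
        rows.append(line.split("\t"))
    if P0 is None or L0 is None:
        raise FormatError(f"{path}: missing P0_uM/L0_uM header lines")
    npts = len(P0)
    resids, domains, dH, dN = [], {}, {}, {}
    for parts in rows:
        res = int(parts[0])
        if res in dH:
            raise FormatError(f"{path}: duplicated residue id {res}")
        vals = [np.nan if v in ("NA", "") else float(v) for v in parts[2 : 2 + 2 * npts]]
        resids.append(res)
        domains[res] = parts[1]
        dH[res] = vals[0::2]
        dN[res] = vals[1::2]
    table = ShiftTable(
        dH=pd.DataFrame.from_dict(dH, orient="index"),
        dN=pd.DataFrame.from_dict(dN, orient="index"),
        P0=np.array(P0), L0=np.array(L0), domains=domains,
    )
    broadened = table.broadened()
    if broadened:
        log.info("%s: %d residue(s) broadened mid-titration: %s", path.name, len(broadened), broadened)
    return table


def write_titration_table(t: ShiftTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# P0_uM: " + " ".join(_FMT % x for x in t.P0) + "\n")
        fh.write("# L0_uM: " + " ".join(_FMT % x for x in t.L0) + "\n")
        cols = [f"{ax}{i}" for i in range(t.n_points) for ax in ("H", "N")]
        fh.write("residue\tdomain\t" + "\t".join(cols) + "\n")
        for res in t.residues:
            vals = []
            for i in range(t.n_points):
                for frame in (t.dH, t.dN):
                    v = frame.loc[res].iloc[i]
                    vals.append("NA" if pd.isna(v) else _FMT % v)
            fh.write(f"{int(res)}\t{t.domains.get(int(res), '')}\t" + "\t".join(vals) + "\n")


# ------------------------------------------------------------- intensity

def read_intensity_table(path: str | Path) -> IntensityTable:
    """Read a relaxation intensity TSV (header: experiment, field,
    delays; one row per residue)."""
    path = Path(path)
    experiment = field = delays = None
    header = None
    resids, mat = [], []
    for line in path.read_text().splitlines():
        if line.startswith("#"):
            if "experiment:" in line:
                experiment = line.split(":", 1)[1].strip()
            elif "field_MHz:" in line:
                field = float(line.split(":", 1)[1])
            elif "delays_s:" in line:
                delays = [float(x) for x in line.split(":", 1)[1].split()]
            continue
        if not line.strip():
            continue
        if header is None:
            header = line
            continue
        parts = line.split("\t")
        resids.append(int(parts[0]))
        mat.append([float(v) for v in parts[1:]])
    if experiment is None or field is None or delays is None:
        raise FormatError(f"{path}: missing experiment/field_MHz/delays_s headers")
    return IntensityTable(np.array(resids), np.array(delays), np.array(mat), experiment, field)


def write_intensity_table(t: IntensityTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# experiment: {t.experiment}\n# field_MHz: {_FMT % t.field_mhz}\n")
        fh.write("# delays_s: " + " ".join(_FMT % d for d in t.delays) + "\n")
        fh.write("residue\t" + "\t".join(f"I{i}" for i in range(len(t.delays))) + "\n")
        for res, row in zip(t.residues, t.intensities):
            fh.write(f"{int(res)}\t" + "\t".join(_FMT % v for v in row) + "\n")


# ----------------------------------------------------------- coordinates

def read_coordinates(path: str | Path) -> BeadModel:
    """Read a single-chain PDB with one Cα (or single bead) per residue.

    Beads are ordered by residue number.  Multiple chains or a residue
    without a Cα/bead atom are format errors (chain breaks rejected).
    """
    st = gemmi.read_pdb(str(path))
    if len(st) == 0 or len(st[0]) == 0:
        raise FormatError(f"{path}: no chains found")
    if len(st[0]) > 1:
        raise FormatError(f"{path}: {len(st[0])} chains; single-chain input required")
    chain = st[0][0]
    entries = []
    for residue in chain:
        atom = residue.find_atom("CA", "*")
        if atom is None:
            if len(residue) == 1:
                atom = residue[0]  # generic single-bead residue
            else:
                raise FormatError(f"{path}: residue {residue.seqid.num} has no CA atom")
        entries.append((residue.seqid.num, [atom.pos.x, atom.pos.y, atom.pos.z],
                        residue.segment or ""))
    entries.sort(key=lambda e: e[0])
    nums = [e[0] for e in entries]
    if len(set(nums)) != len(nums):
        raise FormatError(f"{path}: duplicated residue numbers")
    if nums != list(range(nums[0], nums[0] + len(nums))):
        raise FormatError(f"{path}: non-consecutive residue numbering (chain break)")
    coords = np.array([e[1] for e in entries])
    return BeadModel(coords=coords, residues=np.array(nums),
                     domains=np.array([e[2] for e in entries], dtype=object))


def write_coordinates(m: BeadModel, path: str | Path) -> None:
    """Write the bead model as a Cα-only PDB (domain label in segid)."""
    st = gemmi.Structure()
    st.name = "bead model"
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for res, xyz, dom in zip(m.residues, m.coords, m.domains):
        r = gemmi.Residue()
        r.name = "ALA"
        r.seqid = gemmi.SeqId(int(res), " ")
        r.segment = str(dom)[:4]
        a = gemmi.Atom()
        a.name = "CA"
        a.element = gemmi.Element("C")
        a.pos = gemmi.Position(*xyz)
        r.add_atom(a)
        chain.add_residue(r)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


# ----------------------------------------------------------- config & co

def load_config(path: str | Path | None) -> dict:
    if path is None:
        return {}
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return cfg


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def write_manifest(outdir: str | Path, stage: str, config: dict, seed: int | None,
                   inputs: dict[str, str] | None = None) -> Path:
    """Machine-readable run manifest: stage, config, seed, input digests.

    Byte-identical across reruns with the same seed/config except for the
    timestamp field.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "stage": stage,
        "config": config,
        "seed": seed,
        "inputs": inputs or {},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return path


def write_results(results: dict, outdir: str | Path, config: dict | None = None,
                  seed: int | None = None, inputs: dict[str, str] | None = None) -> list[Path]:
    """Write stage outputs as plain-text tables plus a run manifest.

    Dispatch is on result type: a binding fit becomes a Kd table (one row
    per domain/model), relaxation records and spectral densities a
    per-residue table, Guinier/P(r) results a summary block, and ensemble
    models a ranked table plus Rg histogram.  Unknown dataclasses fall
    back to JSON.  Writes into ``outdir`` (created if needed).
    """
    from .ensemble import EnsembleModel  # local import to avoid a cycle
    from .relaxation import RulerResult
    from .saxs import DmaxScan, GuinierResult, PofR
    from .titration import BindingFit

    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOError(f"cannot create {outdir}: {exc}") from exc
    written = []

    for name, obj in results.items():
        path = outdir / f"{name}.tsv"
        if isinstance(obj, BindingFit):
            with open(path, "w") as fh:
                fh.write("domain\tmodel\tmode\tKd_uM\tKd_sd_uM\tn_residues\tn_excluded\tn_broadened\n")
                for dom, (kd, sd) in sorted(obj.domain_kd.items()):
                    nres = sum(1 for f in obj.residues if f.domain == dom and f.residue not in obj.excluded)
                    fh.write(f"{dom}\t{obj.model}\t{obj.mode}\t{_FMT % kd}\t{_FMT % sd}"
                             f"\t{nres}\t{len(obj.excluded)}\t{len(obj.broadened)}\n")
            res_path = outdir / f"{name}_residues.tsv"
            with open(res_path, "w") as fh:
                fh.write("residue\tdomain\tKd_uM\tKd_err\tdd_bound_ppm\tmax_csp_ppm\tconverged\texcluded\n")
                for f in obj.residues:
                    fh.write(f"{f.residue}\t{f.domain}\t{_FMT % f.Kd}\t{_FMT % f.Kd_err}\t"
                             f"{_FMT % f.dd_bound}\t{_FMT % f.max_csp}\t{int(f.converged)}\t"
                             f"{int(f.residue in obj.excluded)}\n")
            written.append(res_path)
        elif isinstance(obj, list) and obj and isinstance(obj[0], EnsembleModel):
            with open(path, "w") as fh:
                fh.write("rank\tn_states\tchi\tscale\tmembers\tweights\tmember_rgs_A\n")
                for rank, m in enumerate(obj, 1):
                    fh.write(f"{rank}\t{m.n_states}\t{_FMT % m.chi}\t{_FMT % m.scale}\t"
                             + ",".join(map(str, m.members)) + "\t"
                             + ",".join(_FMT % w for w in m.weights) + "\t"
                             + ",".join(_FMT % r for r in m.member_rgs) + "\n")
        elif isinstance(obj, list) and not obj:
            log.warning("result %r is empty; writing empty table", name)
            path.write_text("# empty\n")
        elif isinstance(obj, (GuinierResult, PofR, DmaxScan, RulerResult)):
            d = asdict(obj)
            with open(path, "w") as fh:
                for k, v in d.items():
                    if isinstance(v, np.ndarray):
                        fh.write(f"{k}\t" + "\t".join(_FMT % x for x in v) + "\n")
                    else:
                        fh.write(f"{k}\t{v}\n")
        elif isinstance(obj, pd.DataFrame):
            obj.to_csv(path, sep="\t", float_format=_FMT)
        elif is_dataclass(obj):
            (outdir / f"{name}.json").write_text(json.dumps(asdict(obj), default=str, indent=1))
            written.append(outdir / f"{name}.json")
            continue
        else:
            raise TypeError(f"cannot serialize result {name!r} of type {type(obj)}")
        written.append(path)

    written.append(write_manifest(outdir, stage=",".join(results), config=config or {},
                                  seed=seed, inputs=inputs))
    return written
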