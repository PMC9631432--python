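"""Per-capsid analysis orchestration.

``run_interface_analysis`` takes assembled capsid structures (or files that
expand to one), extracts the tri-dimer, classifies every contacting chain
pair by quasi-symmetry, computes R / H / composition metrics and writes
tabular results.  ``run_flexibility`` extracts the CC (or AB) dimer,
builds the CA structure-based model and summarizes the center-of-mass
distance distribution.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .contacts import ContactParams, contact_set
from .metrics import (DEFAULT_NONPOLAR, KD_NORMALIZED, HydrophobicityScale,
                      InterfaceRecord, interface_record)
from .sbm import (DEFAULT_TEMPERATURE, SimParams, build_sbm,
                  com_distance_trace, run_langevin)
from .structures import (CapsidAssembly, TriDimer, _contact_graph,
                         expand_assembly, extract_tridimer,
                         read_biomt_operators, read_structure)
from .symmetry import classify_interface, relative_transform

log = logging.getLogger("tridimer")

__all__ = ["RunConfig", "analyze_tridimer", "run_interface_analysis",
           "run_flexibility", "flexibility_summary"]


@dataclass
class RunConfig:
    inputs: list = field(default_factory=list)   # paths or CapsidAssembly objects
    family_tags: dict = field(default_factory=dict)  # source_id -> label
    contact_params: ContactParams = field(default_factory=ContactParams)
    scale: HydrophobicityScale = KD_NORMALIZED
    nonpolar: frozenset = DEFAULT_NONPOLAR
    angle_tol: float = 12.0
    force_expand: bool = False
    sim_params: SimParams = field(default_factory=lambda: SimParams(
        temperature=DEFAULT_TEMPERATURE, n_steps=200_000, save_interval=500,
        seed=0))
    dimer_selector: str = "CC"   # which CP2 to simulate: CC or AB
    output_dir: Path | None = None
    seed: int = 0


def _load(item, config: RunConfig) -> CapsidAssembly:
    if isinstance(item, CapsidAssembly):
        return item
    path = Path(item)
    asm = read_structure(path)
    ops = read_biomt_operators(path)
    needs_expansion = config.force_expand or len(asm) < 12
    if ops and len(ops) > 1 and needs_expansion:
        log.info("%s: expanding %d chains with %d operators",
                 path.name, len(asm), len(ops))
        asm = expand_assembly(asm, ops)
    return asm


def analyze_tridimer(td: TriDimer, config: RunConfig | None = None
                     ) -> list[InterfaceRecord]:
    """Metrics and symmetry class for every contacting pair of a tri-dimer."""
    config = config or RunConfig()
    sub = td.as_assembly()
    graph = _contact_graph(sub, config.contact_params)
    records = []
    for (xid, yid) in sorted(graph):
        cx, cy = sub.chain(xid), sub.chain(yid)
        try:
            t = relative_transform(cx, cy)
            cls = classify_interface(t, (cx.conformer, cy.conformer),
                                     config.angle_tol)
        except ValueError:
            cls = "unclassified"
        cs = contact_set(cx, cy, config.contact_params)
        records.append(interface_record(cs, cx, cy, cls,
                                        config.scale, config.nonpolar))
    return records


def _records_frame(records: list[InterfaceRecord], source_id: str,
                   family: str = "") -> pd.DataFrame:
    return pd.DataFrame([{
        "source": source_id,
        "family": family,
        "chain_x": r.pair_id[0], "chain_y": r.pair_id[1],
        "conformer_x": r.conformers[0], "conformer_y": r.conformers[1],
        "interface_class": r.interface_class,
        "n_inter": r.n_inter, "n_intra_x": r.n_intra_x, "n_intra_y": r.n_intra_y,
        "R": r.R, "H": r.H, "nonpolar_fraction": r.nonpolar_fraction,
        "fold_regime": r.fold_regime,
    } for r in records])


def run_interface_analysis(config: RunConfig) -> pd.DataFrame:
    """Full interface analysis for every input capsid.

    Returns the pooled interface table; when ``config.output_dir`` is set,
    writes one TSV per capsid, a pooled scatter table (R, H, class, family)
    and a JSON manifest with parameters and a config hash.
    """
    if not config.inputs:
        raise ValueError("no input structures given")
    frames = []
    failures = {}
    for item in config.inputs:
        name = item.source_id if isinstance(item, CapsidAssembly) else Path(item).stem
        try:
            asm = _load(item, config)
            td = extract_tridimer(asm, config.contact_params, config.angle_tol)
            records = analyze_tridimer(td, config)
            frames.append(_records_frame(records, asm.source_id,
                                         config.family_tags.get(asm.source_id, "")))
        except Exception as exc:  # per-file failures are logged and skipped
            log.error("%s failed: %s", name, exc)
            failures[str(name)] = str(exc)
    if not frames:
        raise RuntimeError(f"all inputs failed: {failures}")
    table = pd.concat(frames, ignore_index=True)

    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        for source, group in table.groupby("source"):
            group.to_csv(out / f"{source}_interfaces.tsv", sep="\t", index=False)
        scatter = table[table.n_inter > 0][
            ["R", "H", "interface_class", "family", "source"]]
        scatter.to_csv(out / "scatter_RH.tsv", sep="\t", index=False)
        _write_manifest(out, config, failures)
    return table


def _config_digest(config: RunConfig) -> str:
    payload = json.dumps({
        "contact": [config.contact_params.method, config.contact_params.cutoff,
                    config.contact_params.min_seq_sep],
        "scale": config.scale.scale_name,
        "angle_tol": config.angle_tol,
        "sim": [config.sim_params.temperature, config.sim_params.timestep,
                config.sim_params.friction, config.sim_params.n_steps,
                config.sim_params.save_interval, config.sim_params.seed],
        "seed": config.seed,
        "dimer_selector": config.dimer_selector,
    }, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_manifest(out: Path, config: RunConfig, failures: dict) -> None:
    checksums = {}
    for item in config.inputs:
        if not isinstance(item, CapsidAssembly) and Path(item).exists():
            digest = hashlib.sha256(Path(item).read_bytes()).hexdigest()[:16]
            checksums[Path(item).name] = digest
    manifest = {
        "config_hash": _config_digest(config),
        "input_checksums": checksums,
        "seed": config.seed,
        "sim_seed": config.sim_params.seed,
        "contact_cutoff_A": config.contact_params.cutoff,
        "min_seq_sep": config.contact_params.min_seq_sep,
        "angle_tol_deg": config.angle_tol,
        "hydrophobicity_scale": config.scale.scale_name,
        "failures": failures,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


# ---------------------------------------------------------------------------
# flexibility


def _select_cp2(td: TriDimer, selector: str) -> CapsidAssembly:
    """The CC (exact two-fold) or AB (quasi-two-fold) dimer of a tri-dimer."""
    sub = td.as_assembly()
    want = tuple(sorted(selector.upper()))
    for iau in td.iau_chains:
        role = f"FLANK-of-{iau.conformer}"
        flank = next(c for c in td.flank_chains if td.roles[c.chain_id] == role)
        pair = tuple(sorted((iau.conformer, flank.conformer)))
        if pair == want:
            return CapsidAssembly([iau, flank], source_id=td.source_id,
                                  provenance="deposited_assembly")
    raise ValueError(f"no {selector} dimer in tri-dimer "
                     f"(roles: {td.roles})")


def run_flexibility(dimer: CapsidAssembly, config: RunConfig | None = None,
                    contact_params: ContactParams | None = None):
    """Simulate a CP2 dimer and return its COM-distance trace.

    ``contact_params`` controls the native-contact definition for the
    model (CA-only inputs need a CA-distance cutoff around 8 A).
    """
    config = config or RunConfig()
    params = contact_params or config.contact_params
    top = build_sbm(dimer, params)
    if config.sim_params.n_steps == 0:  # frozen smoke mode
        frames = top.positions[None, :, :]
        return com_distance_trace(frames, int((top.chain_of == 0).sum()),
                                  top.positions), top
    res = run_langevin(top, config.sim_params)
    n_burn = max(len(res.frames) // 10, 1)
    trace = com_distance_trace(res.frames[n_burn:],
                               int((top.chain_of == 0).sum()),
                               top.positions)
    return trace, top


def flexibility_summary(traces: dict[str, "COMTrace"],
                        output_dir: Path | None = None) -> pd.DataFrame:
    rows = [{"dimer": k, "mean_nm": t.mean, "sd_nm": t.sd,
             "native_nm": t.native_value, "n_frames": len(t.values)}
            for k, t in traces.items()]
    df = pd.DataFrame(rows)
    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "flexibility_summary.tsv", sep="\t", index=False)
        for k, t in traces.items():
            t.to_tsv(out / f"{k}_com_trace.tsv")
    return df
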