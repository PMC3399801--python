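"""Configuration-driven orchestration of the full analysis chain.

A run configuration (YAML or dict) describes synthetic "taxa" — each a
phantom family with a locomotor group, a joint size and a body-mass
distribution — plus morphometry, correction, phylogeny and discriminant
options.  :func:`run_pipeline` executes
VOI → segmentation → morphometry → Tb.Th correction → allometric residuals
→ Blomberg's K → discriminant analysis, writing one CSV per stage and a
structured JSON log.  Outputs are a pure function of the configuration
(every random stage derives its seed from the run seed).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import phantoms
from .allometry import AllometricScaling
from .discriminant import CanonicalDiscriminant
from .morphometry import MorphometryConfig, summarize
from .phylo import PhylogeneticSignal, parse_newick
from .resolution import DEFAULT_CORRECTION, CorrectionModel
from .segmentation import binarize, isodata_threshold
from .voi import extract_spherical_voi, voi_spec_from_surface
from .volume import VolumeImage

__all__ = ["RunConfig", "TaxonSpec", "run_pipeline", "load_config"]

#: trabecular variables entering the statistical stages
ANALYSIS_VARIABLES = ["conn_d_per_mm3", "smi", "tb_n_per_mm",
                      "tb_th_corr_mm", "da"]


@dataclass
class TaxonSpec:
    """One synthetic taxon: phantom family + group label + body-size model."""

    name: str
    group: str
    phantom: dict
    n_specimens: int
    body_mass_kg: float
    body_mass_cv: float = 0.1
    joint_radius_mm: float = 10.0


@dataclass
class RunConfig:
    """Validated run configuration; every random stage carries the run seed."""

    seed: int
    out_dir: str
    taxa: list[TaxonSpec]
    shape: int = 64
    voxel_mm: float = 0.03
    blur_sigma_mm: float = 0.0
    noise_sd: float = 0.0
    morphometry: MorphometryConfig = field(default_factory=MorphometryConfig)
    correction_model: CorrectionModel = field(
        default_factory=lambda: DEFAULT_CORRECTION)
    tree_newick: str | None = None
    stepwise: bool = False
    priors: str = "equal"


def load_config(source) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML path, YAML text, or dict.

    Raises ``ValueError`` for schema violations (missing seed, no taxa,
    malformed taxon entries).
    """
    if isinstance(source, (str, Path)) and Path(str(source)).exists():
        raw = yaml.safe_load(Path(source).read_text())
    elif isinstance(source, str):
        raw = yaml.safe_load(source)
    else:
        raw = dict(source)
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    if "seed" not in raw:
        raise ValueError("config schema: 'seed' is required "
                         "(every random stage must be seeded)")
    if not raw.get("taxa"):
        raise ValueError("config schema: at least one taxon is required")
    taxa = []
    for i, t in enumerate(raw["taxa"]):
        missing = {"name", "group", "phantom", "n_specimens",
                   "body_mass_kg"} - set(t)
        if missing:
            raise ValueError(f"config schema: taxon #{i} missing {sorted(missing)}")
        taxa.append(TaxonSpec(
            name=t["name"], group=t["group"], phantom=dict(t["phantom"]),
            n_specimens=int(t["n_specimens"]),
            body_mass_kg=float(t["body_mass_kg"]),
            body_mass_cv=float(t.get("body_mass_cv", 0.1)),
            joint_radius_mm=float(t.get("joint_radius_mm", 10.0))))
    morph = MorphometryConfig(**raw.get("morphometry", {}))
    corr = raw.get("correction_model")
    model = (CorrectionModel.from_json(corr) if corr else DEFAULT_CORRECTION)
    return RunConfig(
        seed=int(raw["seed"]), out_dir=str(raw.get("out_dir", "trabkit_run")),
        taxa=taxa, shape=int(raw.get("shape", 64)),
        voxel_mm=float(raw.get("voxel_mm", 0.03)),
        blur_sigma_mm=float(raw.get("blur_sigma_mm", 0.0)),
        noise_sd=float(raw.get("noise_sd", 0.0)),
        morphometry=morph, correction_model=model,
        tree_newick=raw.get("tree_newick"),
        stepwise=bool(raw.get("stepwise", False)),
        priors=str(raw.get("priors", "equal")))


def _make_specimen_volume(taxon: TaxonSpec, cfg: RunConfig,
                          seed: int) -> VolumeImage:
    """One phantom realisation for a taxon, with per-specimen geometric jitter."""
    rng = np.random.default_rng(seed)
    params = dict(taxon.phantom)
    kind = params.pop("kind")
    jitter = lambda v: v * float(rng.uniform(0.92, 1.08))  # noqa: E731
    shape = (cfg.shape,) * 3
    if kind == "plates":
        spec = phantoms.PhantomSpec(
            "plates", shape, cfg.voxel_mm,
            plate_thickness_mm=jitter(params["plate_thickness_mm"]),
            plate_spacing_mm=jitter(params["plate_spacing_mm"]),
            orientation_axis=params.get("orientation_axis", "z"), seed=seed)
        vol, _ = phantoms.make_plate_phantom(spec)
    elif kind == "rods":
        spec = phantoms.PhantomSpec(
            "rods", shape, cfg.voxel_mm,
            rod_radius_mm=jitter(params["rod_radius_mm"]),
            pitch_mm=jitter(params["pitch_mm"]),
            orientation_axis=params.get("orientation_axis", "z"), seed=seed)
        vol, _ = phantoms.make_rod_phantom(spec)
    elif kind == "isotropic":
        spec = phantoms.PhantomSpec(
            "isotropic", shape, cfg.voxel_mm,
            target_bvtv=min(0.94, max(0.06, jitter(params["target_bvtv"]))),
            correlation_length_mm=params.get("correlation_length_mm",
                                             8 * cfg.voxel_mm),
            seed=seed)
        vol, _ = phantoms.make_isotropic_phantom(spec)
    else:
        raise ValueError(f"unknown phantom kind {kind!r}")
    return phantoms.degrade(vol, cfg.blur_sigma_mm, cfg.noise_sd, seed=seed + 1)


def run_pipeline(config: RunConfig | dict | str) -> dict:
    """Execute the full chain; returns a report dict and writes the bundle.

    Report keys: ``morphometry`` (per-specimen DataFrame), ``residuals``,
    ``k_table``, ``dfa`` (DiscriminantResults), ``confusion``, ``files``.
    Any stage failure raises with the stage name and specimen id.
    """
    cfg = config if isinstance(config, RunConfig) else load_config(config)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root_ss = np.random.SeedSequence(cfg.seed)
    taxon_seeds = root_ss.spawn(len(cfg.taxa))

    rows = []
    for taxon, t_ss in zip(cfg.taxa, taxon_seeds):
        spec_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                      for s in t_ss.spawn(taxon.n_specimens)]
        mass_rng = np.random.default_rng(
            int(t_ss.generate_state(1)[0] % (2 ** 31)))
        for k, seed in enumerate(spec_seeds):
            sid = f"{taxon.name}_{k:02d}"
            try:
                vol = _make_specimen_volume(taxon, cfg, seed)
                mesh = phantoms.make_joint_mesh(taxon.joint_radius_mm, 1.0)
                voi_spec = voi_spec_from_surface(mesh)
                # place the joint-scaled VOI at the phantom centre, capped
                # to what the synthetic scan can hold
                center = (np.asarray(vol.shape)[::-1] - 1) / 2.0 * cfg.voxel_mm
                edge = min(voi_spec.cube_edge_mm,
                           (cfg.shape - 2) * cfg.voxel_mm)
                voi_spec.center_mm = center
                voi_spec.cube_edge_mm = edge
                voi = extract_spherical_voi(vol, voi_spec)
                mcfg = MorphometryConfig(**{**cfg.morphometry.__dict__,
                                            "seed": seed})
                summ = summarize(voi, mcfg, cfg.correction_model)
            except Exception as exc:
                raise RuntimeError(
                    f"pipeline stage failed for specimen {sid}: {exc}") from exc
            row = {"specimen": sid, "taxon": taxon.name, "group": taxon.group,
                   "body_mass_kg": float(taxon.body_mass_kg * np.exp(
                       mass_rng.normal(0.0, taxon.body_mass_cv)))}
            row.update(summ.to_dict())
            rows.append(row)
    morpho = pd.DataFrame(rows)
    files = {}
    files["morphometry"] = out / "morphometry.csv"
    morpho.to_csv(files["morphometry"], index=False, float_format="%.8g")

    # allometric residualization (pooled log-log OLS per variable); variables
    # with non-positive values (degenerate phantom families can have zero
    # Conn.D or SMI) are log-undefined and excluded with a warning
    usable = [v for v in ANALYSIS_VARIABLES
              if (morpho[v] > 0).all() and np.isfinite(morpho[v]).all()]
    dropped_vars = sorted(set(ANALYSIS_VARIABLES) - set(usable))
    if dropped_vars:
        warnings.warn("excluding log-undefined variables from "
                      f"residualization: {dropped_vars}")
    if not usable:
        raise RuntimeError("pipeline stage 'residuals': no strictly positive "
                           "variables to residualize")
    feats = morpho[usable]
    allo = AllometricScaling(feats, morpho["body_mass_kg"]).fit()
    resid = allo.residuals.copy()
    resid.insert(0, "specimen", morpho["specimen"])
    resid.insert(1, "taxon", morpho["taxon"])
    resid.insert(2, "group", morpho["group"])
    files["residuals"] = out / "residuals.csv"
    resid.to_csv(files["residuals"], index=False, float_format="%.8g")

    # phylogenetic signal on species means
    k_table = None
    taxa_names = [t.name for t in cfg.taxa]
    if len(taxa_names) >= 3:
        if cfg.tree_newick:
            tree = parse_newick(cfg.tree_newick)
        else:  # equal-branch star tree over the synthetic taxa
            tree = parse_newick(
                "(" + ",".join(f"{t}:1.0" for t in taxa_names) + "):0;")
        means = resid.groupby("taxon")[usable].mean()
        k_table = PhylogeneticSignal(tree, means).fit().table
        files["k_table"] = out / "k_table.csv"
        k_table.to_csv(files["k_table"], float_format="%.8g")

    # discriminant analysis by locomotor group
    dfa_model = CanonicalDiscriminant(allo.residuals, morpho["group"],
                                      priors=cfg.priors)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = (dfa_model.fit_stepwise() if cfg.stepwise else dfa_model.fit())
    confusion = res.confusion()
    files["confusion"] = out / "dfa_confusion.csv"
    conf = confusion.counts.copy()
    conf["pct_correct"] = confusion.percent_correct
    conf.to_csv(files["confusion"], float_format="%.8g")
    files["structure"] = out / "dfa_structure.csv"
    res.structure_matrix.to_csv(files["structure"], float_format="%.8g")
    if len(set(morpho["group"])) > 2 and len(res.variables) < \
            len(morpho) - len(set(morpho["group"])):
        pw = res.pairwise_f()
        files["pairwise_f"] = out / "dfa_pairwise_f.csv"
        pw.table().to_csv(files["pairwise_f"])

    log = {"seed": cfg.seed, "n_specimens": len(morpho),
           "variables": ANALYSIS_VARIABLES,
           "thresholds": morpho["threshold"].tolist(),
           "correction": {"slope": cfg.correction_model.slope,
                          "intercept": cfg.correction_model.intercept},
           "overall_pct_correct": confusion.overall_percent,
           "selected": res.selected}
    files["log"] = out / "run_log.json"
    files["log"].write_text(json.dumps(log, indent=2))

    return {"morphometry": morpho, "residuals": resid, "allometry": allo,
            "k_table": k_table, "dfa": res, "confusion": confusion,
            "files": {k: str(v) for k, v in files.items()}}
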