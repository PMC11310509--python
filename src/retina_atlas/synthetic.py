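"""Ground-truth synthetic developing-retina atlas.

The generator emulates the statistical structure the downstream stages
assume, with every planted feature recoverable from config + seed:

* per-class Gaussian birth-age distributions, with the periphery lagging the
  macula by a configurable number of days;
* a sampling design of (age, location) samples spanning post-conception
  weeks ~8-22, with per-cell class labels drawn in proportion to each
  class's birth density at that sample's age and location;
* a per-cell latent maturation in [0, 1] that rises logistically with age
  (macula ahead of periphery), exposed as latent time for progenitors;
* negative-binomial counts (mean-dispersion parameterization,
  var = mu + mu^2/theta) with planted class markers, three latent-time gene
  modules (decreasing / peaked / increasing), fate-biased TFs in neurogenic
  progenitors, and location DEGs with stated natural-log fold changes;
* peaks within the linkage window whose pseudobulk accessibility is an
  affine function of the linked gene's expression plus noise, and decoy
  peaks outside every window;
* a gene-level accessibility matrix whose module-gene trajectories lead
  expression on latent time by a configurable offset;
* a 10-dimensional embedding with velocity vectors pointing from each
  neurogenic progenitor toward the terminal region of its planted fate;
* an adult reference holding the same classes at maturation 1.0.

A second, unrelated export, :func:`table1_fixture`, encodes the published
summary of transcription-factor fate predictions (predicted class plus
literature status) used to validate the TF-specification step.
"""
from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import norm

from .io import CountMatrix, NormState, dump_config, write_bed, write_cell_table, write_counts, write_json

PROGENITOR_CLASSES = ("PRPC", "NRPC")
TERMINAL_CLASSES = ("RGC", "AC", "HC", "Cone", "Rod", "BC", "MG")


@dataclasses.dataclass(frozen=True)
class ClassSpec:
    """One major class: macula birth-age mean/sd in days."""

    name: str
    birth_mean: float
    birth_sd: float
    progenitor: bool = False


DEFAULT_CLASSES = (
    ClassSpec("PRPC", 80.0, 12.0, progenitor=True),
    ClassSpec("NRPC", 85.0, 12.0, progenitor=True),
    ClassSpec("RGC", 78.0, 10.0),
    ClassSpec("AC", 84.0, 10.0),
    ClassSpec("HC", 88.0, 10.0),
    ClassSpec("Cone", 92.0, 10.0),
    ClassSpec("Rod", 105.0, 12.0),
    ClassSpec("BC", 112.0, 10.0),
    ClassSpec("MG", 118.0, 10.0),
)

#: sampling ages (days post conception); each age is sampled in both
#: locations, giving a design of paired macula/periphery samples.
DEFAULT_SAMPLE_AGES = (56, 70, 84, 98, 112, 126, 140, 154)


@dataclasses.dataclass
class AtlasConfig:
    """Parameters of the synthetic atlas; defaults define the demo dataset."""

    n_cells: int = 12000
    n_genes: int = 600
    classes: tuple = DEFAULT_CLASSES
    macula_lag_days: float = 14.0
    sample_ages: tuple = DEFAULT_SAMPLE_AGES
    nb_dispersion: float = 10.0
    marker_effect: float = 10.0
    n_markers_per_class: int = 14
    n_immature_markers: int = 10
    n_module_genes: int = 40
    module_amplitude: float = 8.0
    module_r_floor: float = 0.3
    tf_effect: float = 2.0
    deg_lfc: float = 2.0
    n_location_degs: int = 30
    linkage_window_bp: int = 250_000
    n_linked_peaks: int = 120
    n_decoy_peaks: int = 120
    peak_noise_sd: float = 0.35
    chromatin_lead: float = 0.15
    maturation_tau: float = 18.0
    progenitor_tau: float = 10.0
    progenitor_mid_offset: float = 0.0
    latent_jitter_days: float = 6.0
    n_adult_per_class: int = 120
    seed: int = 0

    def __post_init__(self) -> None:
        if self.macula_lag_days < 0:
            raise ValueError("macula_lag_days must be non-negative")
        if self.n_cells < 1 or self.n_genes < 1:
            raise ValueError("n_cells and n_genes must be positive")
        for c in self.classes:
            if c.birth_sd <= 0:
                raise ValueError(f"class {c.name}: birth sd must be > 0")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.marker_effect < 1:
            raise ValueError("marker_effect is a fold change >= 1")
        needed = (
            len(self.classes) * (self.n_markers_per_class + self.n_immature_markers)
            + 3 * self.n_module_genes
            + 2 * len(TERMINAL_CLASSES)
            + self.n_location_degs
        )
        if self.n_genes < needed + 10:
            raise ValueError(
                f"n_genes={self.n_genes} too small for planted structure "
                f"(needs >= {needed + 10})"
            )


@dataclasses.dataclass
class GroundTruth:
    """Planted structure, fully determined by config + seed."""

    true_class: np.ndarray
    maturity: np.ndarray
    fate: np.ndarray  # '' for cells without a planted fate
    module_label: np.ndarray  # per gene: 1..3 or 0 (none)
    tf_map: dict  # TF gene name -> fated class
    deg_lfc: dict  # gene name -> signed natural-log fold change (macula/periphery)
    peak_links: dict  # peak_id -> linked gene name (absent => decoy)
    birth_means: dict  # (class, location) -> planted birth mean (days)


@dataclasses.dataclass
class Atlas:
    """Bundle of everything the pipeline consumes."""

    cells: pd.DataFrame
    counts: CountMatrix
    gene_acc: CountMatrix
    peak_acc: pd.DataFrame  # peaks x pseudobulk units (log2-normalized scale)
    peaks: pd.DataFrame
    gene_anchors: pd.DataFrame  # gene, contig, position (TSS)
    embedding: np.ndarray
    velocities: np.ndarray
    adult_counts: CountMatrix
    adult_labels: np.ndarray
    truth: GroundTruth
    config: AtlasConfig


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def _module_shape(k: int, t: np.ndarray) -> np.ndarray:
    """Mean-expression shape of module k over latent time t in [0,1]."""
    if k == 1:  # decreasing
        return 1.0 - t
    if k == 2:  # interior peak, slightly early so the trend test sees it
        return np.exp(-((t - 0.42) ** 2) / (2 * 0.16**2))
    if k == 3:  # increasing
        return t
    raise ValueError(k)


def _gene_names(cfg: AtlasConfig) -> tuple[list, dict]:
    """Lay out the gene panel; returns names and index blocks."""
    names: list[str] = []
    blocks: dict = {"mature": {}, "immature": {}, "module": {}, "tf": {}, "deg": []}
    for c in cfg.classes:
        idx = []
        for i in range(cfg.n_markers_per_class):
            idx.append(len(names))
            names.append(f"{c.name}_mat{i}")
        blocks["mature"][c.name] = np.array(idx)
        idx = []
        for i in range(cfg.n_immature_markers):
            idx.append(len(names))
            names.append(f"{c.name}_imm{i}")
        blocks["immature"][c.name] = np.array(idx)
    for k in (1, 2, 3):
        idx = []
        for i in range(cfg.n_module_genes):
            idx.append(len(names))
            names.append(f"MOD{k}_{i}")
        blocks["module"][k] = np.array(idx)
    for fate in TERMINAL_CLASSES:
        idx = []
        for i in range(2):
            idx.append(len(names))
            names.append(f"TF_{fate}_{i}")
        blocks["tf"][fate] = np.array(idx)
    for i in range(cfg.n_location_degs):
        blocks["deg"].append(len(names))
        names.append(f"LOCDEG_{i}")
    blocks["deg"] = np.array(blocks["deg"])
    i = 0
    while len(names) < cfg.n_genes:
        names.append(f"HK_{i}")
        i += 1
    return names, blocks


def _expression_rates(
    cfg: AtlasConfig,
    blocks: dict,
    base: np.ndarray,
    classes: np.ndarray,
    maturity: np.ndarray,
    latent: np.ndarray,
    fate: np.ndarray,
    location: np.ndarray,
) -> np.ndarray:
    """Per-gene x per-cell NB mean rates implied by the planted structure."""
    n_cells = len(classes)
    rates = np.tile(0.25 * base[:, None], (1, n_cells))
    progen = np.isin(classes, PROGENITOR_CLASSES)
    # markers switch on (or off) log-linearly at staggered maturation
    # onsets — sequential gene activation, so a group's overlap with the
    # adult program, and hence its similarity to the adult, grows smoothly
    # and monotonically with maturation
    gamma = np.log(cfg.marker_effect)
    onset_width = 0.15
    for c in (spec.name for spec in cfg.classes):
        in_c = classes == c
        if not in_c.any():
            continue
        n_mat = len(blocks["mature"][c])
        onsets = np.linspace(0.05, 0.8, n_mat)
        for g, tau in zip(blocks["mature"][c], onsets):
            act = _logistic((maturity[in_c] - tau) / onset_width)
            rates[g, in_c] = base[g] * 0.5 * np.exp(gamma * act)
        n_imm = len(blocks["immature"][c])
        offsets = np.linspace(0.2, 0.95, n_imm)
        for g, tau in zip(blocks["immature"][c], offsets):
            act = 1.0 - _logistic((maturity[in_c] - tau) / onset_width)
            rates[g, in_c] = base[g] * 0.5 * np.exp(gamma * act)
    for k in (1, 2, 3):
        shape = _module_shape(k, latent)
        for g in blocks["module"][k]:
            # module genes are well-expressed in progenitors so their
            # latent-time trend is resolvable above counting noise
            rates[g, progen] = 3.0 * base[g] * (0.3 + cfg.module_amplitude * shape[progen])
    nrpc = classes == "NRPC"
    for f in TERMINAL_CLASSES:
        for g in blocks["tf"][f]:
            rates[g, nrpc] = base[g]
            rates[g, nrpc & (fate == f)] = base[g] * cfg.tf_effect
    prpc = classes == "PRPC"
    half = cfg.n_location_degs // 2
    for j, g in enumerate(blocks["deg"]):
        sign = 1.0 if j < half else -1.0
        rates[g, prpc] = base[g] * np.where(
            location[prpc] == "macula",
            np.exp(sign * cfg.deg_lfc / 2),
            np.exp(-sign * cfg.deg_lfc / 2),
        )
    return rates


def _nb_counts(rng: np.random.Generator, rates: np.ndarray, theta: float) -> sp.csr_matrix:
    lam = rng.gamma(theta, rates / theta)
    return sp.csr_matrix(rng.poisson(lam))


def generate_atlas(config: AtlasConfig | None = None) -> Atlas:
    """Generate the full synthetic atlas from a config.

    Deterministic: the same config (including seed) reproduces byte-identical
    outputs.
    """
    cfg = config or AtlasConfig()
    rng = np.random.default_rng(cfg.seed)
    class_specs = {c.name: c for c in cfg.classes}

    # --- sampling design -> cells --------------------------------------
    # Per-sample cell counts follow the total birth density at that sample's
    # age and location (earlier samples are smaller, as in real tissue); this
    # makes each class's age distribution proportional to its own Gaussian on
    # the grid, so planted birth means are recoverable from member ages.
    samples = [(age, loc) for age in cfg.sample_ages for loc in ("macula", "periphery")]
    weights = []
    for age, loc in samples:
        mus = np.array(
            [
                c.birth_mean + (cfg.macula_lag_days if loc == "periphery" else 0.0)
                for c in cfg.classes
            ]
        )
        sds = np.array([c.birth_sd for c in cfg.classes])
        weights.append(norm.pdf(age, loc=mus, scale=sds).sum())
    weights = np.asarray(weights)
    if weights.sum() <= 0:
        raise ValueError("no class has support anywhere on the sampling design")
    n_per = np.maximum(1, np.round(cfg.n_cells * weights / weights.sum()).astype(int))
    # adjust largest samples so totals match n_cells exactly
    while n_per.sum() != cfg.n_cells:
        j = int(np.argmax(n_per))
        n_per[j] += 1 if n_per.sum() < cfg.n_cells else -1

    rows = []
    for (age, loc), n_s in zip(samples, n_per):
        mus = np.array(
            [
                c.birth_mean + (cfg.macula_lag_days if loc == "periphery" else 0.0)
                for c in cfg.classes
            ]
        )
        sds = np.array([c.birth_sd for c in cfg.classes])
        dens = norm.pdf(age, loc=mus, scale=sds)
        if dens.sum() <= 0:
            raise ValueError(
                f"no class has support at sample age {age} ({loc}); "
                "class proportions cannot sum to 1"
            )
        probs = dens / dens.sum()
        labels = rng.choice([c.name for c in cfg.classes], size=n_s, p=probs)
        for lab in labels:
            rows.append((age, loc, lab))
    ages = np.array([r[0] for r in rows], dtype=float)
    locs = np.array([r[1] for r in rows])
    classes = np.array([r[2] for r in rows])
    n_cells = len(rows)

    # --- per-cell maturation / latent time ------------------------------
    # progenitors progress on a slower clock with a later midpoint, so their
    # latent time traverses the whole [0, 1] range over the sampling window
    lag = np.where(locs == "periphery", cfg.macula_lag_days, 0.0)
    progen_mask = np.isin(classes, PROGENITOR_CLASSES)
    offsets = np.where(progen_mask, cfg.progenitor_mid_offset, 10.0)
    mids = np.array([class_specs[c].birth_mean for c in classes]) + lag + offsets
    taus = np.where(progen_mask, cfg.progenitor_tau, cfg.maturation_tau)
    jitter = rng.normal(0.0, cfg.latent_jitter_days, n_cells)
    maturity = 0.97 * _logistic((ages + jitter - mids) / taus)

    # --- fates for neurogenic progenitors --------------------------------
    fate = np.full(n_cells, "", dtype=object)
    nrpc_idx = np.flatnonzero(classes == "NRPC")
    if len(nrpc_idx):
        f_mus = np.array([class_specs[f].birth_mean for f in TERMINAL_CLASSES])
        f_sds = np.array([class_specs[f].birth_sd for f in TERMINAL_CLASSES])
        for i in nrpc_idx:
            dens = norm.pdf(ages[i], loc=f_mus + lag[i], scale=f_sds)
            fate[i] = rng.choice(TERMINAL_CLASSES, p=dens / dens.sum())

    # --- counts ----------------------------------------------------------
    gene_names, blocks = _gene_names(cfg)
    base = rng.gamma(2.0, 1.5, cfg.n_genes) + 0.5
    size_factor = np.exp(rng.normal(0.0, 0.2, n_cells))
    rates = _expression_rates(cfg, blocks, base, classes, maturity, maturity, fate, locs)
    counts = _nb_counts(rng, rates * size_factor[None, :], cfg.nb_dispersion)
    cell_ids = [f"cell_{i:05d}" for i in range(n_cells)]
    cm = CountMatrix(counts, gene_names, cell_ids, NormState.RAW)

    # --- gene-level accessibility (leads expression on latent time) -----
    lead_latent = np.clip(maturity + cfg.chromatin_lead, 0.0, 1.0)
    acc_rates = _expression_rates(cfg, blocks, base, classes, maturity, lead_latent, fate, locs)
    gene_acc = CountMatrix(
        _nb_counts(rng, acc_rates * size_factor[None, :], cfg.nb_dispersion),
        gene_names,
        cell_ids,
        NormState.RAW,
    )

    # --- cell table ------------------------------------------------------
    cluster = np.where(classes == "NRPC", np.char.add("NRPC_", fate.astype(str)), classes)
    cells = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "sample_id": [f"s{a}_{l[:3]}" for a, l in zip(ages.astype(int), locs)],
            "age_days": ages.astype(int),
            "pcw_group": (ages // 7).astype(int),
            "location": locs,
            "major_class": classes,
            "subclass": classes,
            "cluster": cluster,
            "latent_time": maturity,
            "fate": fate,
        }
    )

    # --- genomic layout, peaks, pseudobulk accessibility -----------------
    genes_per_contig = 50
    contig = np.array([f"ctg{g // genes_per_contig + 1}" for g in range(cfg.n_genes)])
    anchor = np.array(
        [200_000 + (g % genes_per_contig) * 600_000 for g in range(cfg.n_genes)],
        dtype=np.int64,
    )
    gene_anchors = pd.DataFrame({"gene": gene_names, "contig": contig, "position": anchor})

    # pseudobulk units: sample x major class, min 10 cells
    pb = cells.groupby(["sample_id", "major_class"]).indices
    units = {k: v for k, v in pb.items() if len(v) >= 10}
    unit_names = [f"{s}|{c}" for s, c in units]
    log_expr = np.log1p(
        1e6
        * cm.dense()
        / np.maximum(np.asarray(cm.matrix.sum(axis=0)).ravel(), 1)[None, :]
    )
    expr_pb = np.column_stack([log_expr[:, idx].mean(axis=1) for idx in units.values()])

    # linked peaks attach to the planted structured genes (markers, modules)
    structured = np.concatenate(
        [blocks["mature"][c] for c in class_specs]
        + [blocks["module"][k] for k in (1, 2, 3)]
    )
    linked_genes = structured[: cfg.n_linked_peaks]
    peak_rows = []
    acc_rows = []
    links = {}
    for j, g in enumerate(linked_genes):
        pid = f"peak_linked_{j}"
        offset = int(rng.integers(-cfg.linkage_window_bp // 2, cfg.linkage_window_bp // 2))
        start = int(max(0, anchor[g] + offset))
        peak_rows.append((pid, contig[g], start, start + 501))
        e = expr_pb[g]
        z = (e - e.mean()) / (e.std() + 1e-12)
        acc_rows.append(z + rng.normal(0.0, cfg.peak_noise_sd, len(unit_names)))
        links[pid] = gene_names[g]
    for j in range(cfg.n_decoy_peaks):
        g = int(rng.integers(0, cfg.n_genes))
        pid = f"peak_decoy_{j}"
        start = int(anchor[g] + 280_000)  # outside every gene's linkage window
        peak_rows.append((pid, contig[g], start, start + 501))
        acc_rows.append(rng.normal(0.0, 1.0, len(unit_names)))
    peaks = pd.DataFrame(peak_rows, columns=["peak_id", "contig", "start", "end"])
    peak_acc = pd.DataFrame(
        np.array(acc_rows), index=peaks["peak_id"], columns=unit_names
    )

    # --- embedding + velocities ------------------------------------------
    dim = 10
    centroids = {c.name: rng.normal(0.0, 1.0, dim) * 8.0 for c in cfg.classes}
    X = np.zeros((n_cells, dim))
    V = np.zeros((n_cells, dim))
    noise = rng.normal(0.0, 0.8, (n_cells, dim))
    for i in range(n_cells):
        c = classes[i]
        if c == "PRPC":
            # corridor from the progenitor pole toward the neurogenic pole
            X[i] = centroids["PRPC"] + maturity[i] * (
                centroids["NRPC"] - centroids["PRPC"]
            )
            target = centroids["NRPC"]
        elif c == "NRPC":
            f = fate[i]
            X[i] = centroids["NRPC"] + 0.6 * maturity[i] * (centroids[f] - centroids["NRPC"])
            target = centroids[f]
        else:
            # differentiated cells continue the same corridor: immature cells
            # sit near the neurogenic pole, mature cells at the class pole,
            # so the kNN graph is connected from progenitors to terminals
            X[i] = (1.0 - maturity[i]) * centroids["NRPC"] + maturity[i] * centroids[c]
            target = centroids[c]
        V[i] = target - X[i]
    X += noise
    vnorm = np.linalg.norm(V, axis=1, keepdims=True)
    V = V / np.maximum(vnorm, 1e-12) + rng.normal(0.0, 0.05, (n_cells, dim))

    # --- adult reference --------------------------------------------------
    adult_classes = np.repeat(
        [c for c in TERMINAL_CLASSES], cfg.n_adult_per_class
    ).astype(object)
    n_adult = len(adult_classes)
    adult_mat = np.full(n_adult, 1.0)
    adult_loc = np.full(n_adult, "whole")
    adult_fate = np.full(n_adult, "", dtype=object)
    adult_rates = _expression_rates(
        cfg, blocks, base, adult_classes, adult_mat, adult_mat, adult_fate, adult_loc
    )
    adult_sf = np.exp(rng.normal(0.0, 0.2, n_adult))
    adult_counts = CountMatrix(
        _nb_counts(rng, adult_rates * adult_sf[None, :], cfg.nb_dispersion),
        gene_names,
        [f"adult_{i:05d}" for i in range(n_adult)],
        NormState.RAW,
    )

    # --- ground truth -----------------------------------------------------
    module_label = np.zeros(cfg.n_genes, dtype=int)
    for k in (1, 2, 3):
        module_label[blocks["module"][k]] = k
    tf_map = {
        gene_names[g]: f for f in TERMINAL_CLASSES for g in blocks["tf"][f]
    }
    half = cfg.n_location_degs // 2
    deg_truth = {
        gene_names[g]: (cfg.deg_lfc if j < half else -cfg.deg_lfc)
        for j, g in enumerate(blocks["deg"])
    }
    birth_means = {}
    for c in cfg.classes:
        birth_means[(c.name, "macula")] = c.birth_mean
        birth_means[(c.name, "periphery")] = c.birth_mean + cfg.macula_lag_days
    truth = GroundTruth(
        true_class=classes,
        maturity=maturity,
        fate=fate,
        module_label=module_label,
        tf_map=tf_map,
        deg_lfc=deg_truth,
        peak_links=links,
        birth_means=birth_means,
    )

    return Atlas(
        cells=cells,
        counts=cm,
        gene_acc=gene_acc,
        peak_acc=peak_acc,
        peaks=peaks,
        gene_anchors=gene_anchors,
        embedding=X,
        velocities=V,
        adult_counts=adult_counts,
        adult_labels=adult_classes,
        truth=truth,
        config=cfg,
    )


def write_atlas(atlas: Atlas, outdir) -> None:
    """Write the atlas to plain-text files (MTX/TSV/BED/JSON/YAML)."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_counts(atlas.counts, out / "counts.mtx", out / "genes.txt", out / "cells.txt")
    write_counts(
        atlas.gene_acc, out / "gene_acc.mtx", out / "genes.txt", out / "cells.txt"
    )
    write_cell_table(atlas.cells, out / "cells.tsv")
    write_bed(atlas.peaks, out / "peaks.bed")
    atlas.peak_acc.to_csv(out / "peak_acc.tsv", sep="\t")
    atlas.gene_anchors.to_csv(out / "gene_anchors.tsv", sep="\t", index=False)
    np.savetxt(out / "embedding.tsv", atlas.embedding, delimiter="\t")
    np.savetxt(out / "velocities.tsv", atlas.velocities, delimiter="\t")
    write_counts(
        atlas.adult_counts,
        out / "adult_counts.mtx",
        out / "genes.txt",
        out / "adult_cells.txt",
    )
    pd.DataFrame(
        {"cell_id": atlas.adult_counts.cells, "major_class": atlas.adult_labels}
    ).to_csv(out / "adult_labels.tsv", sep="\t", index=False)
    write_json(
        {
            "module_label": dict(zip(atlas.counts.genes, atlas.truth.module_label)),
            "tf_map": atlas.truth.tf_map,
            "deg_lfc": atlas.truth.deg_lfc,
            "peak_links": atlas.truth.peak_links,
            "birth_means": {f"{c}|{l}": v for (c, l), v in atlas.truth.birth_means.items()},
        },
        out / "ground_truth.json",
    )
    cfg = dataclasses.asdict(atlas.config)
    cfg["classes"] = [dataclasses.asdict(c) for c in atlas.config.classes]
    cfg["sample_ages"] = list(atlas.config.sample_ages)
    dump_config(cfg, out / "config.yaml")


# ---------------------------------------------------------------------------
# Dedicated small simulators for the calibration-style checks


def simulate_location_counts(
    n_cells_per_loc: int,
    n_genes: int,
    n_degs: int = 0,
    lfc: float = 2.0,
    base_mean: float = 1.5,
    nb_dispersion: float = 10.0,
    age_span: tuple = (56, 154),
    seed: int = 0,
):
    """Two-location NB counts for one class, with optional planted DEGs.

    With ``n_degs=0`` both locations share identical NB generators (a null
    instrument for false-positive calibration).  Planted DEGs get a signed
    natural-log macula/periphery fold change of ``lfc`` (half up, half down).
    Returns (CountMatrix raw, cell table, truth dict gene -> signed lfc).
    """
    rng = np.random.default_rng(seed)
    n = 2 * n_cells_per_loc
    locs = np.array(["macula"] * n_cells_per_loc + ["periphery"] * n_cells_per_loc)
    ages = rng.integers(age_span[0], age_span[1] + 1, n)
    base = rng.gamma(2.0, base_mean / 2.0, n_genes) + 0.3
    rates = np.tile(base[:, None], (1, n))
    truth = {}
    half = n_degs // 2
    for j in range(n_degs):
        sign = 1.0 if j < half else -1.0
        mult = np.where(locs == "macula", np.exp(sign * lfc / 2), np.exp(-sign * lfc / 2))
        rates[j] *= mult
        truth[f"g{j:04d}"] = sign * lfc
    sf = np.exp(rng.normal(0.0, 0.2, n))
    counts = _nb_counts(rng, rates * sf[None, :], nb_dispersion)
    genes = [f"g{j:04d}" for j in range(n_genes)]
    cells = pd.DataFrame(
        {
            "cell_id": [f"c{i:05d}" for i in range(n)],
            "age_days": ages,
            "pcw_group": ages // 7,
            "location": locs,
            "major_class": "PRPC",
        }
    )
    return CountMatrix(counts, genes, cells["cell_id"].tolist(), NormState.RAW), cells, truth


def simulate_marker_accessibility(
    n_classes: int = 4,
    n_marker_peaks_per_class: int = 10,
    n_background_peaks: int = 60,
    n_replicates: int = 5,
    effect_log2: float = 2.0,
    noise_sd: float = 0.25,
    seed: int = 0,
):
    """Peak x pseudobulk log2 accessibility with planted class-specific peaks.

    Marker peaks of class c are ``effect_log2`` higher (log2 scale) in that
    class's replicates.  Returns (DataFrame peaks x units, unit class labels,
    truth dict peak_id -> class).
    """
    rng = np.random.default_rng(seed)
    classes = [f"class{k}" for k in range(n_classes)]
    units = [f"{c}_rep{r}" for c in classes for r in range(n_replicates)]
    unit_class = np.repeat(classes, n_replicates)
    n_peaks = n_classes * n_marker_peaks_per_class + n_background_peaks
    baseline = rng.uniform(2.0, 4.0, n_peaks)
    acc = baseline[:, None] + rng.normal(0.0, noise_sd, (n_peaks, len(units)))
    truth = {}
    row = 0
    names = []
    for c in classes:
        for j in range(n_marker_peaks_per_class):
            pid = f"{c}_marker{j}"
            acc[row, unit_class == c] += effect_log2
            truth[pid] = c
            names.append(pid)
            row += 1
    for j in range(n_background_peaks):
        names.append(f"bg{j}")
        row += 1
    return pd.DataFrame(acc, index=names, columns=units), unit_class, truth


def planted_phase_trajectories(n_grid: int = 101):
    """Piecewise trajectories with phase switches at 25/50/75% of the grid.

    Quarters: primed (chromatin open, gene silent), coupled-on (both rise),
    coupled-off (both fall), decoupled (chromatin falls, expression rises).
    Returns (t, c, u, s, true_phases, boundary_positions).
    """
    t = np.linspace(0.0, 1.0, n_grid)
    q = n_grid // 4
    c = np.empty(n_grid)
    s = np.empty(n_grid)
    # primed: c high & rising slightly, s ~ 0
    c[:q] = 0.8 + 0.1 * t[:q] / t[q]
    s[:q] = 0.0
    # coupled-on: both rise (expression starts clearly above the silence floor)
    ramp = np.linspace(0, 1, 2 * q - q, endpoint=False)
    c[q : 2 * q] = 0.9 + 0.6 * ramp
    s[q : 2 * q] = 0.08 + 0.84 * ramp
    # coupled-off: both fall
    ramp = np.linspace(0, 1, 3 * q - 2 * q, endpoint=False)
    c[2 * q : 3 * q] = 1.5 - 0.7 * ramp
    s[2 * q : 3 * q] = 0.92 - 0.5 * ramp
    # decoupled: c falls, s rises
    m = n_grid - 3 * q
    ramp = np.linspace(0, 1, m)
    c[3 * q :] = 0.8 - 0.5 * ramp
    s[3 * q :] = 0.42 + 0.5 * ramp
    u = s.copy()
    true_phases = np.array(
        ["primed"] * q + ["coupled_on"] * q + ["coupled_off"] * q + ["decoupled"] * m
    )
    return t, c, u, s, true_phases, np.array([q, 2 * q, 3 * q])


# ---------------------------------------------------------------------------
# Published TF fate-prediction summary (fixture)

# Rows: TF, predicted class, status, literature classes (empty => Unknown).
# Glia-promoting TFs are excluded from the source table by construction.
_TABLE1 = [
    # AC
    ("PRDM13", "AC", "Matched", ("AC",)),
    ("HES6", "AC", "Unmatched", ("Rod",)),
    ("POU2F2", "AC", "Unmatched", ("Cone",)),
    ("ID2", "AC", "Unknown", ()),
    ("ST18", "AC", "Unknown", ()),
    # BC
    ("NFIB", "BC", "Matched", ("BC",)),
    ("OTX2", "BC", "Matched", ("BC",)),
    ("PRDM8", "BC", "Matched", ("BC",)),
    ("VSX1", "BC", "Matched", ("BC",)),
    ("VSX2", "BC", "Matched", ("BC",)),
    ("NEUROD1", "BC", "Unmatched", ("Cone", "Rod")),
    ("RORA", "BC", "Unknown", ()),
    ("SKOR2", "BC", "Unknown", ()),
    # Cone
    ("FOXN4", "Cone", "Matched", ("Cone",)),
    ("PRDM1", "Cone", "Matched", ("Cone",)),
    ("THRB", "Cone", "Matched", ("Cone",)),
    ("ID3", "Cone", "Unknown", ()),
    ("CUX2", "Cone", "Unknown", ()),
    ("FOS", "Cone", "Unknown", ()),
    ("FOSB", "Cone", "Unknown", ()),
    ("MEIS2", "Cone", "Unknown", ()),
    ("NPAS3", "Cone", "Unknown", ()),
    ("NR4A1", "Cone", "Unknown", ()),
    ("NR4A3", "Cone", "Unknown", ()),
    ("RUNX1", "Cone", "Unknown", ()),
    ("RXRG", "Cone", "Unknown", ()),
    # HC
    ("ONECUT1", "HC", "Matched", ("HC",)),
    ("ONECUT2", "HC", "Matched", ("HC",)),
    ("PROX1", "HC", "Matched", ("HC",)),
    ("TFAP2A", "HC", "Matched", ("HC",)),
    ("TFAP2B", "HC", "Matched", ("HC",)),
    ("EBF1", "HC", "Unknown", ()),
    ("ESRRB", "HC", "Unknown", ()),
    ("ESRRG", "HC", "Unknown", ()),
    ("HIVEP3", "HC", "Unknown", ()),
    ("MYT1L", "HC", "Unknown", ()),
    ("ONECUT3", "HC", "Unknown", ()),
    ("PRDM6", "HC", "Unknown", ()),
    ("TSHZ2", "HC", "Unknown", ()),
    ("TSHZ3", "HC", "Unknown", ()),
    ("ZFHX3", "HC", "Unknown", ()),
    ("ZFPM2", "HC", "Unknown", ()),
    # RGC
    ("ATOH7", "RGC", "Matched", ("RGC",)),
    ("ISL1", "RGC", "Matched", ("RGC",)),
    ("PBX4", "RGC", "Matched", ("RGC",)),
    ("POU4F2", "RGC", "Matched", ("RGC",)),
    ("EGR1", "RGC", "Unmatched", ("AC", "HC")),
    ("ZIC1", "RGC", "Unmatched", ("Rod",)),
    ("E2F7", "RGC", "Unknown", ()),
    ("EBF2", "RGC", "Unknown", ()),
    ("EBF3", "RGC", "Unknown", ()),
    ("FOXM1", "RGC", "Unknown", ()),
    ("HES5", "RGC", "Unknown", ()),
    ("LEF1", "RGC", "Unknown", ()),
    ("MECOM", "RGC", "Unknown", ()),
    ("MXD3", "RGC", "Unknown", ()),
    ("MYBL1", "RGC", "Unknown", ()),
    ("PAX5", "RGC", "Unknown", ()),
    ("PBX3", "RGC", "Unknown", ()),
    ("POU6F2", "RGC", "Unknown", ()),
    ("SOX5", "RGC", "Unknown", ()),
    ("SP8", "RGC", "Unknown", ()),
    ("TFAP2D", "RGC", "Unknown", ()),
    ("ZNF367", "RGC", "Unknown", ()),
    ("ZNF730", "RGC", "Unknown", ()),
    # Rod
    ("CRX", "Rod", "Matched", ("Rod",)),
    ("HMGA2", "Rod", "Matched", ("Rod",)),
    ("NR2E3", "Rod", "Matched", ("Rod",)),
    ("NRL", "Rod", "Matched", ("Rod",)),
    ("HES1", "Rod", "Unmatched", ("Cone",)),
    ("MEF2C", "Rod", "Unmatched", ("Cone",)),
    ("NFIA", "Rod", "Unmatched", ("BC",)),
    ("NFIX", "Rod", "Unmatched", ("BC",)),
    ("RARB", "Rod", "Unmatched", ("RGC",)),
    ("ARID5B", "Rod", "Unknown", ()),
    ("ASCL1", "Rod", "Unknown", ()),
    ("BACH2", "Rod", "Unknown", ()),
    ("BHLHE41", "Rod", "Unknown", ()),
    ("CREB5", "Rod", "Unknown", ()),
    ("EPAS1", "Rod", "Unknown", ()),
    ("ETV1", "Rod", "Unknown", ()),
    ("ETV5", "Rod", "Unknown", ()),
    ("GLIS3", "Rod", "Unknown", ()),
    ("HIF3A", "Rod", "Unknown", ()),
    ("JAZF1", "Rod", "Unknown", ()),
    ("MITF", "Rod", "Unknown", ()),
    ("NR3C2", "Rod", "Unknown", ()),
    ("PAX2", "Rod", "Unknown", ()),
    ("PAX8", "Rod", "Unknown", ()),
    ("PPARA", "Rod", "Unknown", ()),
    ("RAX2", "Rod", "Unknown", ()),
    ("RREB1", "Rod", "Unknown", ()),
    ("SOX6", "Rod", "Unknown", ()),
    ("TCF7L1", "Rod", "Unknown", ()),
    ("ZBTB7C", "Rod", "Unknown", ()),
]


def table1_fixture() -> pd.DataFrame:
    """Published TF annotation table: predicted class, validation status,
    and literature class(es) for mismatches.

    Columns: tf, predicted_class, status (Matched/Unmatched/Unknown),
    literature_classes (tuple, empty for Unknown).
    """
    df = pd.DataFrame(
        _TABLE1, columns=["tf", "predicted_class", "status", "literature_classes"]
    )
    assert not df["tf"].duplicated().any()
    return df
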