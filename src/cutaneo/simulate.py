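"""Synthetic triplet-matched cutaneous cohorts with known ground truth.

The generator emulates the statistical structure a psoriasis skin-microbiome
analysis assumes: 51 matched triplets (lesion / contralateral unaffected /
site-matched control), two latent community types ("cutaneotypes") whose
mixing depends on clinical skin type, lesion-associated enrichment of the
four major skin genera (Corynebacterium, Propionibacterium, Staphylococcus,
Streptococcus), presence/absence marker OTUs depleted in lesions, a shared
subject effect encoding the matched design, Dirichlet-multinomial
compositional noise, and variable sequencing depth (lognormal, median about
8,600 reads). Every random choice flows from two integer seeds so identical
configurations yield byte-identical tables, and a :class:`SimulationTruth`
ledger records the latent variables that recovery tests assert against.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .io import (
    RANKS,
    SKIN_TYPES,
    CountTable,
    SampleMetadata,
    TaxonomyTable,
)

#: The four major skin-associated genera whose combined abundance rises in
#: lesional skin.
SKIN_GENERA = ("Corynebacterium", "Propionibacterium", "Staphylococcus", "Streptococcus")

#: Genera hosting the designated presence/absence marker OTUs.
MARKER_GENERA = ("Gp4", "Schlegelella")

_PHYLA = ("Proteobacteria", "Actinobacteria", "Firmicutes", "Bacteroidetes")


@dataclass
class SimulationConfig:
    """Parameters of the cohort generator.

    Defaults state the cohort the analysis targets: 51 triplets, 500 OTUs in
    40 genera, lognormal depths with median ~8,600 reads, cutaneotype-2
    probability 0.30/0.50/0.60 for control/unaffected/lesion, a 1.6-fold
    lesion multiplier on the skin-genera block, and marker prevalence
    0.78/0.53/0.20.
    """

    n_triplets: int = 51
    n_otus: int = 500
    n_genera: int = 40
    tree_seed: int = 0
    cohort_seed: int = 0
    depth_log_mean: float = float(np.log(8600.0))
    depth_log_sd: float = 0.42
    dirichlet_concentration: float = 50.0
    type2_probability: dict = field(
        default_factory=lambda: {"control": 0.30, "unaffected": 0.50, "lesion": 0.60}
    )
    skin_genera_multiplier: dict = field(
        default_factory=lambda: {"control": 1.0, "unaffected": 1.0, "lesion": 1.6}
    )
    marker_prevalence: dict = field(
        default_factory=lambda: {"control": 0.78, "unaffected": 0.53, "lesion": 0.20}
    )
    #: relative-abundance share each marker OTU takes when present
    marker_shares: tuple = (0.008, 0.005)
    subject_effect_sd: float = 0.30
    severity_coupling: float = 0.5
    #: optional override; two probability vectors over genera (rows)
    cutaneotype_base_compositions: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_otus < 3:
            raise ValueError("n_otus must be >= 3")
        if self.n_genera < len(SKIN_GENERA) + len(MARKER_GENERA):
            raise ValueError("n_genera too small for the named genera")
        if self.dirichlet_concentration <= 0:
            raise ValueError("dirichlet_concentration must be > 0")
        for d in (self.type2_probability, self.marker_prevalence):
            for k, v in d.items():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"rate {k}={v} outside [0, 1]")
        for k, v in self.skin_genera_multiplier.items():
            if v <= 0:
                raise ValueError(f"multiplier {k}={v} must be > 0")
        if self.cutaneotype_base_compositions is not None:
            bc = np.asarray(self.cutaneotype_base_compositions, dtype=float)
            if bc.shape != (2, self.n_genera) or not np.allclose(bc.sum(axis=1), 1.0):
                raise ValueError(
                    "cutaneotype_base_compositions must be two probability "
                    "vectors over the genera"
                )


def null_config(**overrides) -> SimulationConfig:
    """A configuration with every group effect switched off.

    Skin types are exchangeable: equal cutaneotype mixing, unit skin-genera
    multipliers, equal marker prevalence. Used for type-I-error calibration.
    """
    cfg = SimulationConfig(
        type2_probability={t: 0.45 for t in SKIN_TYPES},
        skin_genera_multiplier={t: 1.0 for t in SKIN_TYPES},
        marker_prevalence={t: 0.50 for t in SKIN_TYPES},
        **overrides,
    )
    return cfg


@dataclass
class SimulationTruth:
    """Ground-truth ledger written alongside every simulated cohort."""

    cutaneotype: pd.Series            # per sample: 1 or 2
    subject_effects: dict             # subject_id -> per-genus log effect
    genus_of_otu: pd.Series           # per OTU
    marker_otus: list                 # OTU ids of the designated markers
    skin_genus_otus: list             # OTU ids in the four skin genera
    marker_present: pd.DataFrame      # samples x markers boolean
    severity: pd.DataFrame            # lesion subjects x (PASI, BSA, PGA)
    tree_seed: int = 0
    cohort_seed: int = 0

    def to_json_dict(self) -> dict:
        return {
            "cutaneotype": self.cutaneotype.to_dict(),
            "subject_effects": {k: list(map(float, v)) for k, v in self.subject_effects.items()},
            "genus_of_otu": self.genus_of_otu.to_dict(),
            "marker_otus": list(self.marker_otus),
            "skin_genus_otus": list(self.skin_genus_otus),
            "marker_present": {c: self.marker_present[c].astype(bool).to_dict()
                               for c in self.marker_present.columns},
            "severity": {c: self.severity[c].to_dict() for c in self.severity.columns},
            "tree_seed": self.tree_seed,
            "cohort_seed": self.cohort_seed,
        }


# ---------------------------------------------------------------------------
# Genus / taxonomy layout
# ---------------------------------------------------------------------------

def genus_layout(n_otus: int, n_genera: int) -> tuple[list, pd.Series, pd.DataFrame]:
    """Deterministic assignment of OTUs to genera and genera to phyla.

    OTUs of one genus are contiguous, so the tree builder can make each
    genus a clade. Returns (genus names, genus-of-OTU series, genus table
    with phylum column).
    """
    named = list(SKIN_GENERA) + list(MARKER_GENERA)
    genera = named + [f"Genus{i:03d}" for i in range(n_genera - len(named))]
    phylum_of = {}
    phylum_of["Corynebacterium"] = "Actinobacteria"
    phylum_of["Propionibacterium"] = "Actinobacteria"
    phylum_of["Staphylococcus"] = "Firmicutes"
    phylum_of["Streptococcus"] = "Firmicutes"
    phylum_of["Gp4"] = "Acidobacteria"
    phylum_of["Schlegelella"] = "Proteobacteria"
    for i, g in enumerate(genera[len(named):]):
        phylum_of[g] = _PHYLA[i % len(_PHYLA)]

    base, extra = divmod(n_otus, n_genera)
    sizes = [base + (1 if i < extra else 0) for i in range(n_genera)]
    otu_ids, otu_genus = [], []
    k = 0
    for g, size in zip(genera, sizes):
        for _ in range(size):
            otu_ids.append(f"OTU{k:04d}")
            otu_genus.append(g)
            k += 1
    genus_of_otu = pd.Series(otu_genus, index=otu_ids, name="genus")
    gtab = pd.DataFrame({"genus": genera, "phylum": [phylum_of[g] for g in genera]})
    return genera, genus_of_otu, gtab


def make_taxonomy(genus_of_otu: pd.Series, gtab: pd.DataFrame) -> TaxonomyTable:
    phylum_of = dict(zip(gtab["genus"], gtab["phylum"]))
    rows = {}
    for otu, g in genus_of_otu.items():
        ph = phylum_of[g]
        rows[otu] = {
            "phylum": ph,
            "class": f"{ph}_cl",
            "order": f"{ph}_or",
            "family": f"{g}_fam",
            "genus": g,
        }
    df = pd.DataFrame.from_dict(rows, orient="index")[list(RANKS)]
    return TaxonomyTable(df)


# ---------------------------------------------------------------------------
# Tree
# ---------------------------------------------------------------------------

def _yule_topology(labels: list, rng: np.random.Generator) -> TreeNode:
    """Pure-birth topology over the given tip labels.

    Starting from one lineage, a uniformly random extant lineage splits at
    each step until every label has a tip.
    """
    if len(labels) == 1:
        return TreeNode(name=labels[0])
    root = TreeNode()
    leaves = [root]
    while len(leaves) < len(labels):
        i = int(rng.integers(len(leaves)))
        node = leaves.pop(i)
        left, right = TreeNode(), TreeNode()
        node.extend([left, right])
        leaves.extend([left, right])
    for leaf, lab in zip(leaves, labels):
        leaf.name = lab
    return root


def make_tree(n_otus: int, tree_seed: int, n_genera: int = 40) -> TreeNode:
    """Random rooted phylogeny with genus-monophyletic OTU clades.

    A Yule backbone over genera carries one Yule subtree per genus;
    branch lengths are exponential with mean 0.1 (arbitrary units).
    """
    if n_otus < 3:
        raise ValueError("n_otus must be >= 3")
    rng = np.random.default_rng(tree_seed)
    genera, genus_of_otu, _ = genus_layout(n_otus, n_genera)
    backbone = _yule_topology(list(genera), rng)
    for tip in list(backbone.tips()):
        members = genus_of_otu.index[genus_of_otu == tip.name].tolist()
        sub = _yule_topology(members, rng)
        if sub.is_tip():
            tip.name = sub.name
        else:
            tip.name = None
            tip.extend(list(sub.children))
    tree = backbone
    for node in tree.traverse(include_self=False):
        node.length = float(rng.exponential(0.1))
    tree.length = None
    return tree


# ---------------------------------------------------------------------------
# Base compositions
# ---------------------------------------------------------------------------

def default_base_compositions(gtab: pd.DataFrame) -> np.ndarray:
    """Two genus-level probability vectors defining the cutaneotypes.

    Type 1 is Proteobacteria-dominated; type 2 is Firmicutes/Actinobacteria
    dominated (where the four skin genera live). Within each phylum block
    mass decays geometrically, giving a realistic uneven community. The
    skin-genera block carries ~15% of type-1 mass and ~35% of type-2 mass so
    that a 70/30 control mixture has combined skin-genera abundance near
    22% and a lesion mixture with the 1.6x multiplier lands near 34%.
    """
    genera = gtab["genus"].tolist()
    phyla = gtab["phylum"].tolist()
    n = len(genera)

    def build(dominant: set, dominant_mass: float, skin_mass: float) -> np.ndarray:
        w = np.zeros(n)
        skin_idx = [i for i, g in enumerate(genera) if g in SKIN_GENERA]
        dom_idx = [i for i, (g, p) in enumerate(zip(genera, phyla))
                   if p in dominant and g not in SKIN_GENERA]
        rest_idx = [i for i in range(n) if i not in skin_idx and i not in dom_idx]
        for idx, mass in ((skin_idx, skin_mass), (dom_idx, dominant_mass),
                          (rest_idx, 1.0 - skin_mass - dominant_mass)):
            if not idx:
                continue
            geo = 0.75 ** np.arange(len(idx))
            w[idx] = mass * geo / geo.sum()
        return w / w.sum()

    t1 = build({"Proteobacteria"}, dominant_mass=0.60, skin_mass=0.15)
    t2 = build({"Firmicutes", "Actinobacteria"}, dominant_mass=0.45, skin_mass=0.35)
    return np.vstack([t1, t2])


def _otu_split_weights(genus_of_otu: pd.Series) -> pd.Series:
    """Deterministic within-genus OTU weights (geometric, ratio 0.6)."""
    parts = []
    for g, members in genus_of_otu.groupby(genus_of_otu):
        geo = 0.6 ** np.arange(len(members))
        parts.append(pd.Series(geo / geo.sum(), index=members.index))
    return pd.concat(parts).loc[genus_of_otu.index]


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

_SITES = ("body", "head", "upper extremity", "lower extremity")
_SEVERITY_ANCHORS = {"PASI": (8.7, 10.1), "BSA": (9.4, 13.9), "PGA": (6.6, 6.9)}


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def simulate_cohort(config: SimulationConfig, *, _shared_effects: dict | None = None,
                    _multiplier_override: dict | None = None,
                    _triplet_ids: list | None = None, _week: int | None = None,
                    _rng: np.random.Generator | None = None):
    """Generate one cross-sectional cohort.

    Returns ``(CountTable, SampleMetadata, TaxonomyTable, PhylogeneticTree,
    SimulationTruth)``. The private keyword arguments let the longitudinal
    wrapper share subject effects and shrink multipliers across visits.
    """
    cfg = config
    rng = _rng if _rng is not None else np.random.default_rng(cfg.cohort_seed)
    genera, genus_of_otu, gtab = genus_layout(cfg.n_otus, cfg.n_genera)
    tree = make_tree(cfg.n_otus, cfg.tree_seed, cfg.n_genera)
    taxonomy = make_taxonomy(genus_of_otu, gtab)

    base = (np.asarray(cfg.cutaneotype_base_compositions, dtype=float)
            if cfg.cutaneotype_base_compositions is not None
            else default_base_compositions(gtab))
    if np.any(base.sum(axis=1) == 0):
        raise ValueError("degenerate config: all-zero base composition")
    multipliers = dict(_multiplier_override or cfg.skin_genera_multiplier)

    otu_ids = genus_of_otu.index.tolist()
    otu_w = _otu_split_weights(genus_of_otu).to_numpy()
    genus_index = {g: i for i, g in enumerate(genera)}
    otu_genus_idx = genus_of_otu.map(genus_index).to_numpy()
    skin_mask_genus = np.array([g in SKIN_GENERA for g in genera])
    marker_otus = [genus_of_otu.index[genus_of_otu == g][0] for g in MARKER_GENERA]
    marker_pos = [otu_ids.index(m) for m in marker_otus]
    skin_genus_otus = genus_of_otu.index[genus_of_otu.isin(SKIN_GENERA)].tolist()

    triplet_ids = _triplet_ids or [f"T{t:02d}" for t in range(cfg.n_triplets)]
    n_trip = len(triplet_ids)

    counts = {}
    meta_rows = {}
    latent = {}
    marker_present_rows = {}
    effects = {} if _shared_effects is None else _shared_effects
    severity_rows = {}

    sev_params = {k: _lognormal_params(*v) for k, v in _SEVERITY_ANCHORS.items()}

    for t, tid in enumerate(triplet_ids):
        patient = f"P_{tid}"
        control_subj = f"C_{tid}"
        if patient not in effects:
            effects[patient] = rng.normal(0.0, cfg.subject_effect_sd, cfg.n_genera)
            effects[control_subj] = rng.normal(0.0, cfg.subject_effect_sd, cfg.n_genera)
        site = _SITES[int(rng.integers(len(_SITES)))]
        # head is sebaceous; trunk sites mix, extremities are dry
        if site == "head":
            microenv = "sebaceous"
        elif site == "body":
            microenv = "sebaceous" if rng.random() < 0.5 else "dry"
        else:
            microenv = "dry"
        month = int(rng.integers(1, 13))
        year = int(rng.integers(2008, 2012))
        age_patient = float(np.clip(rng.normal(45.0, 15.0), 18.0, 85.0))
        age_control = float(np.clip(age_patient + rng.uniform(-5, 5), 18.0, 85.0))
        gender = "F" if rng.random() < 0.5 else "M"
        ethnicity = ("white", "black", "asian", "hispanic")[int(rng.integers(4))]
        history = bool(rng.random() < 0.3)

        for skin_type in SKIN_TYPES:
            sid = f"{tid}.{skin_type}"
            subj = control_subj if skin_type == "control" else patient
            ctype = 2 if rng.random() < cfg.type2_probability[skin_type] else 1
            latent[sid] = ctype

            gp = base[ctype - 1] * np.exp(effects[subj])
            mult = multipliers[skin_type]
            gp = np.where(skin_mask_genus, gp * mult, gp)
            gp = gp / gp.sum()
            p_otu = gp[otu_genus_idx] * otu_w

            present = rng.random() < cfg.marker_prevalence[skin_type]
            marker_present_rows[sid] = [present, present]
            # Dirichlet-multinomial noise on the community; present markers
            # take a fixed small share so presence is observable at depth.
            p_otu[marker_pos] = 0.0
            alpha = cfg.dirichlet_concentration * p_otu / p_otu.sum()
            comp = rng.dirichlet(np.where(alpha > 0, alpha, 1e-9))
            comp[p_otu == 0] = 0.0
            comp = comp / comp.sum()
            if present:
                share = np.array(cfg.marker_shares)
                comp = comp * (1.0 - share.sum())
                comp[marker_pos] = share
            depth = max(int(np.round(rng.lognormal(cfg.depth_log_mean, cfg.depth_log_sd))), 1)
            counts[sid] = rng.multinomial(depth, comp)

            row = {
                "skin_type": skin_type,
                "triplet_id": tid,
                "subject_id": subj,
                "body_site": site,
                "microenvironment": microenv,
                "sample_month_year": f"{year}-{month:02d}",
                "age": round(age_control if skin_type == "control" else age_patient, 1),
                "gender": gender,
                "ethnicity": ethnicity,
                "family_history": history,
                "week": 0 if _week is None else _week,
            }
            if skin_type == "lesion":
                depletion = 1.0 - np.mean(marker_present_rows[sid])
                sev = {}
                for score, (mu, sig) in sev_params.items():
                    shift = cfg.severity_coupling * (depletion - 0.5)
                    sev[score] = float(rng.lognormal(mu + shift, sig))
                severity_rows[patient] = sev
                row.update({k: round(v, 2) for k, v in sev.items()})
            else:
                row.update({"PASI": np.nan, "BSA": np.nan, "PGA": np.nan})
            meta_rows[sid] = row

    table = CountTable(pd.DataFrame(counts, index=otu_ids))
    meta = pd.DataFrame.from_dict(meta_rows, orient="index")
    meta.index.name = "sample_id"
    chimera = pd.Series(False, index=otu_ids)
    metadata = SampleMetadata(meta, chimera_flags=chimera)
    truth = SimulationTruth(
        cutaneotype=pd.Series(latent),
        subject_effects=effects,
        genus_of_otu=genus_of_otu,
        marker_otus=marker_otus,
        skin_genus_otus=skin_genus_otus,
        marker_present=pd.DataFrame.from_dict(
            marker_present_rows, orient="index", columns=marker_otus),
        severity=pd.DataFrame.from_dict(severity_rows, orient="index"),
        tree_seed=cfg.tree_seed,
        cohort_seed=cfg.cohort_seed,
    )
    return table, metadata, taxonomy, tree, truth


# ---------------------------------------------------------------------------
# Longitudinal simulation
# ---------------------------------------------------------------------------

ALLOWED_WEEKS = (0, 12, 36)
DEFAULT_ATTRITION = {0: 17, 12: 17, 36: 9}


def simulate_longitudinal(config: SimulationConfig, weeks=(0, 12, 36),
                          treatment_effect: float = 0.5,
                          transient_overshoot: float = 0.0,
                          attrition: dict | None = None) -> dict:
    """Per-week cohorts sharing subject identities.

    ``treatment_effect`` is the fraction by which lesion/unaffected
    skin-genera multipliers shrink toward the control multiplier at each
    follow-up visit; ``transient_overshoot`` optionally inflates the
    unaffected multiplier at week 12 (the rise-then-fall pattern).
    Attrition defaults to 17 triplets at weeks 0 and 12 and 9 at week 36.
    Returns ``{week: (table, metadata, taxonomy, tree, truth)}``.
    """
    for w in weeks:
        if w not in ALLOWED_WEEKS:
            raise ValueError(f"week {w} not in {ALLOWED_WEEKS}")
    attr = dict(DEFAULT_ATTRITION if attrition is None else attrition)
    shared_effects: dict = {}
    all_triplets = [f"T{t:02d}" for t in range(config.n_triplets)]
    base_mult = dict(config.skin_genera_multiplier)
    out = {}
    for w in sorted(weeks):
        visit = ALLOWED_WEEKS.index(w)
        shrink = (1.0 - treatment_effect) ** visit
        mult = {
            t: base_mult["control"] + (base_mult[t] - base_mult["control"]) * shrink
            for t in SKIN_TYPES
        }
        if w == 12 and transient_overshoot > 0:
            mult["unaffected"] *= 1.0 + transient_overshoot
        n_keep = min(attr.get(w, config.n_triplets), config.n_triplets)
        rng = np.random.default_rng((config.cohort_seed, w))
        out[w] = simulate_cohort(
            config,
            _shared_effects=shared_effects,
            _multiplier_override=mult,
            _triplet_ids=all_triplets[:n_keep],
            _week=w,
            _rng=rng,
        )
    return out
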