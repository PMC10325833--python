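"""Synthetic paired gut/oral cohort generator with planted ground truth.

Emulates the study design the rest of the pipeline analyses: a cohort of
paired gut and oral 16S genus-level profiles in which

* each site is a finite mixture of community types ("enterotypes" /
  "orotypes"), modelled as Dirichlet components that differ by a boosted
  driver genus (gut: *Bifidobacterium*, *Ruminococcus*, *Prevotella*;
  oral: *Neisseria*, *Prevotella*, *Streptococcus*);
* sequencing depth varies across samples around a mean of 66,902 reads
  (negative-binomial, so prevalence filtering is non-trivial);
* a handful of taxa occurring at both sites (*Eubacterium*_g11,
  *Actinomyces*, *Atopobium*, *Enterococcus* by default) share a per-subject
  lognormal latent factor, inducing positive gut-oral rank correlation;
* a block of universally prevalent "core" taxa and a block of sparse "rare"
  taxa (per-sample presence probability well below the 30% prevalence
  criterion) give the core-microbiome filter true positives and negatives.

Counts are drawn multinomially from the per-sample Dirichlet probability,
so every downstream stage (normalisation, 0.01% filtering, sqrt-JSD/PAM
typing, prevalence core, cross-site correlation, pathway projection) sees
data with known labels, latent factors and core membership.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .abundance_io import AbundanceTable, PairedCohort
from .function_projection import GeneCopyReference

__all__ = [
    "ComponentSpec", "CohortSpec", "GroundTruth",
    "generate_cohort", "preset", "generate_pathway_reference",
    "default_pathway_reference", "PRESET_NAMES",
]


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComponentSpec:
    """One mixture component (community type) at one body site.

    ``base_concentration`` maps taxon id -> Dirichlet concentration (> 0);
    the concentrations of ``driver_taxa`` are multiplied by ``driver_boost``
    (> 1), making each driver the component's dominant genus.
    """

    weight: float
    base_concentration: dict[str, float]
    driver_taxa: tuple[str, ...] = ()
    driver_boost: float = 15.0

    def __post_init__(self) -> None:
        if not 0 < self.weight <= 1:
            raise ValueError(f"component weight must be in (0, 1], got {self.weight}")
        if not self.base_concentration:
            raise ValueError("base_concentration must be non-empty")
        for taxon, c in self.base_concentration.items():
            if c <= 0:
                raise ValueError(f"concentration for {taxon!r} must be > 0")
        missing = set(self.driver_taxa) - set(self.base_concentration)
        if missing:
            raise ValueError(f"driver taxa absent from concentrations: {sorted(missing)}")
        if self.driver_taxa and self.driver_boost <= 1:
            raise ValueError("driver_boost must be > 1")

    def concentration(self) -> dict[str, float]:
        """Effective concentrations with the driver boost applied."""
        conc = dict(self.base_concentration)
        for t in self.driver_taxa:
            conc[t] *= self.driver_boost
        return conc


@dataclass(frozen=True)
class CohortSpec:
    """Full parameterisation of a paired synthetic cohort."""

    n_subjects: int
    gut_components: tuple[ComponentSpec, ...]
    oral_components: tuple[ComponentSpec, ...]
    depth_mean: float = 66902.0
    depth_dispersion: float = 10.0
    #: taxon id -> lognormal sigma of the shared per-subject coupling factor
    coupled_taxa: dict[str, float] = field(default_factory=dict)
    core_block: tuple[str, ...] = ()
    rare_block: tuple[str, ...] = ()
    #: per-sample presence probability of rare-block taxa (< 0.3)
    rare_presence: float = 0.15
    pathway_ref: GeneCopyReference | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not self.gut_components or not self.oral_components:
            raise ValueError("component lists must be non-empty")
        for name, comps in (("gut", self.gut_components),
                            ("oral", self.oral_components)):
            total = sum(c.weight for c in comps)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} component weights sum to {total}, not 1")
        if self.depth_mean <= 0 or self.depth_dispersion <= 0:
            raise ValueError("depth_mean and depth_dispersion must be > 0")
        if not 0 <= self.rare_presence < 0.3:
            raise ValueError("rare_presence must lie in [0, 0.3)")
        gut_taxa = set(self.gut_taxa)
        oral_taxa = set(self.oral_taxa)
        for t, sigma in self.coupled_taxa.items():
            if sigma < 0:
                raise ValueError(f"coupling sigma for {t!r} must be >= 0")
            if t not in gut_taxa or t not in oral_taxa:
                raise ValueError(f"coupled taxon {t!r} must occur at both sites")
        if self.pathway_ref is not None:
            ref_taxa = set(self.pathway_ref.taxon_ids)
            missing = (gut_taxa | oral_taxa) - ref_taxa
            if missing:
                raise ValueError(
                    f"pathway_ref lacks {len(missing)} cohort taxa, e.g. "
                    f"{sorted(missing)[:3]}")

    @property
    def gut_taxa(self) -> tuple[str, ...]:
        return tuple(self.gut_components[0].base_concentration)

    @property
    def oral_taxa(self) -> tuple[str, ...]:
        return tuple(self.oral_components[0].base_concentration)

    # -- key-value serialisation (pathway_ref travels separately as TSV) ----
    def to_yaml(self, path) -> None:
        import yaml

        def comp(c: ComponentSpec) -> dict:
            return {"weight": c.weight,
                    "base_concentration": dict(c.base_concentration),
                    "driver_taxa": list(c.driver_taxa),
                    "driver_boost": c.driver_boost}

        data = {
            "n_subjects": self.n_subjects,
            "gut_components": [comp(c) for c in self.gut_components],
            "oral_components": [comp(c) for c in self.oral_components],
            "depth_mean": self.depth_mean,
            "depth_dispersion": self.depth_dispersion,
            "coupled_taxa": dict(self.coupled_taxa),
            "core_block": list(self.core_block),
            "rare_block": list(self.rare_block),
            "rare_presence": self.rare_presence,
            "seed": self.seed,
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        import yaml

        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        for key in ("gut_components", "oral_components"):
            data[key] = tuple(
                ComponentSpec(c["weight"], c["base_concentration"],
                              tuple(c.get("driver_taxa", ())),
                              c.get("driver_boost", 15.0))
                for c in data[key])
        for key in ("core_block", "rare_block"):
            data[key] = tuple(data.get(key, ()))
        return cls(**data)


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure of a generated cohort."""

    gut_labels: np.ndarray          # (n,) component index per subject
    oral_labels: np.ndarray         # (n,)
    coupled_taxa: tuple[str, ...]
    latent_factors: np.ndarray      # (n, n_coupled) lognormal draws
    true_core: tuple[str, ...]      # planted universally-prevalent taxa
    true_rare: tuple[str, ...]      # planted sparse taxa
    #: expected gut pathway abundances implied by the per-subject Dirichlet
    #: means, or None when the spec carries no reference
    true_pathway_table: np.ndarray | None = None


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_cohort(spec: CohortSpec) -> tuple[PairedCohort, GroundTruth]:
    """Draw a paired cohort from ``spec``; deterministic under ``spec.seed``.

    Per subject and site: a component is drawn from the mixture weights; the
    component's boosted concentrations are multiplied by the subject's shared
    lognormal factor on each coupled taxon; rare-block taxa are knocked out
    with probability ``1 - rare_presence``; a probability vector is drawn
    from the resulting Dirichlet, a depth from a negative binomial with mean
    ``depth_mean``, and counts multinomially.

    All randomness flows from ``spec.seed`` through one substream for the
    cohort-level draws (labels, latent factors) plus one substream per
    subject-site pair, so adding subjects never reshuffles earlier samples.
    """
    n = spec.n_subjects
    root = np.random.SeedSequence(spec.seed)
    children = root.spawn(1 + 2 * n)
    global_rng = np.random.default_rng(children[0])

    gut_w = [c.weight for c in spec.gut_components]
    oral_w = [c.weight for c in spec.oral_components]
    gut_labels = global_rng.choice(len(gut_w), size=n, p=gut_w)
    oral_labels = global_rng.choice(len(oral_w), size=n, p=oral_w)

    coupled = tuple(spec.coupled_taxa)
    sigmas = np.array([spec.coupled_taxa[t] for t in coupled])
    z = global_rng.standard_normal((n, len(coupled)))
    # mean-one lognormal so coupling shifts no marginal on average
    factors = np.exp(z * sigmas - 0.5 * sigmas ** 2) if coupled else \
        np.ones((n, 0))

    rare = set(spec.rare_block)
    site_conc = {
        "gut": [c.concentration() for c in spec.gut_components],
        "oral": [c.concentration() for c in spec.oral_components],
    }
    site_taxa = {"gut": spec.gut_taxa, "oral": spec.oral_taxa}
    labels = {"gut": gut_labels, "oral": oral_labels}
    counts = {s: np.zeros((n, len(site_taxa[s]))) for s in ("gut", "oral")}
    expected_gut = np.zeros((n, len(site_taxa["gut"])))

    for s in range(n):
        for site_idx, site in enumerate(("gut", "oral")):
            rng = np.random.default_rng(children[1 + 2 * s + site_idx])
            taxa = site_taxa[site]
            conc = site_conc[site][labels[site][s]]
            alpha = np.array([conc[t] for t in taxa])
            for j, t in enumerate(coupled):
                k = taxa.index(t)
                alpha[k] *= factors[s, j]
            present = np.ones(len(taxa), dtype=bool)
            for k, t in enumerate(taxa):
                if t in rare:
                    present[k] = rng.random() < spec.rare_presence
            a = alpha[present]
            p = np.zeros(len(taxa))
            p[present] = rng.dirichlet(a)
            if site == "gut":
                e = np.where(present, alpha, 0.0)
                expected_gut[s] = e / e.sum()
            r = spec.depth_dispersion
            depth = max(1, int(rng.negative_binomial(
                r, r / (r + spec.depth_mean))))
            counts[site][s] = rng.multinomial(depth, p)

    subjects = tuple(f"S{i + 1:03d}" for i in range(n))
    gut_table = AbundanceTable(
        tuple(f"G{i + 1:03d}" for i in range(n)), site_taxa["gut"],
        counts["gut"], site="gut", mode="counts")
    oral_table = AbundanceTable(
        tuple(f"O{i + 1:03d}" for i in range(n)), site_taxa["oral"],
        counts["oral"], site="oral", mode="counts")
    pairing = {s: (g, o) for s, g, o in
               zip(subjects, gut_table.sample_ids, oral_table.sample_ids)}
    cohort = PairedCohort(gut_table, oral_table, subjects, pairing)

    true_pathways = None
    if spec.pathway_ref is not None:
        ref = spec.pathway_ref
        idx = {t: i for i, t in enumerate(ref.taxon_ids)}
        cols = [idx[t] for t in site_taxa["gut"]]
        true_pathways = expected_gut @ ref.copies[cols, :]

    truth = GroundTruth(gut_labels=gut_labels, oral_labels=oral_labels,
                        coupled_taxa=coupled, latent_factors=factors,
                        true_core=tuple(spec.core_block),
                        true_rare=tuple(spec.rare_block),
                        true_pathway_table=true_pathways)
    return cohort, truth


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

#: taxa shared by both sites and planted as universally prevalent; the first
#: four carry the cross-site coupling by default
_SHARED_CORE = (
    "Eubacterium_g11", "Actinomyces", "Atopobium", "Enterococcus",
    "Veillonella", "Haemophilus", "Rothia", "Fusobacterium",
    "Granulicatella", "Gemella", "Lactobacillus", "Dialister",
)

_COUPLED_SIGMA = 1.2

_GUT_DRIVERS = ("Bifidobacterium", "Ruminococcus", "Prevotella")
_ORAL_DRIVERS = ("Neisseria", "Prevotella", "Streptococcus")

_GUT_GENERA = (
    "Bacteroides", "Faecalibacterium", "Blautia", "Roseburia", "Anaerostipes",
    "Eubacterium_g5", "Dorea", "Coprococcus", "Collinsella", "Akkermansia",
    "Alistipes", "Parabacteroides", "Phascolarctobacterium", "Subdoligranulum",
    "Oscillibacter", "Megamonas", "Megasphaera", "Sutterella",
    "Butyricicoccus", "Clostridium_g24", "Romboutsia", "Agathobacter",
    "Fusicatenibacter", "Holdemanella", "Catenibacterium", "Christensenella",
    "Intestinibacter", "Turicibacter", "Odoribacter", "Streptococcus",
)

_ORAL_GENERA = (
    "Porphyromonas", "Capnocytophaga", "Leptotrichia", "Campylobacter",
    "Aggregatibacter", "Corynebacterium", "Selenomonas", "Tannerella",
    "Treponema", "Lautropia", "Kingella", "Abiotrophia", "Oribacterium",
    "Solobacterium", "Stomatobaculum", "Mogibacterium",
    "Lachnoanaerobaculum", "Peptostreptococcus", "Parvimonas", "Eikenella",
)

_N_FILLER = {"gut": 80, "oral": 50}
_N_SHARED_FILLER = 20
_N_RARE = 20

PRESET_NAMES = ("gut-paper", "oral-paper", "study", "null-single-component")


def _panel(site: str) -> tuple[tuple[str, ...], dict[str, float],
                               tuple[str, ...]]:
    """Taxon panel, base concentrations and rare block for one site.

    Concentrations follow a decaying series so that relative abundances are
    realistically uneven and the deep filler tail falls under the 0.01%
    mean-abundance filter.
    """
    drivers = _GUT_DRIVERS if site == "gut" else _ORAL_DRIVERS
    named = _GUT_GENERA if site == "gut" else _ORAL_GENERA
    named = tuple(g for g in named if g not in drivers)
    shared_filler = tuple(f"PAC{700000 + i}_g" for i in range(_N_SHARED_FILLER))
    offset = 100000 if site == "gut" else 200000
    filler = tuple(f"PAC{offset + i}_g" for i in range(_N_FILLER[site]))
    rare = tuple(f"PAC{900000 + i}_g" for i in range(_N_RARE))

    conc: dict[str, float] = {}
    for t in drivers:
        conc[t] = 1.2
    for t in _SHARED_CORE:
        conc.setdefault(t, 0.8)
    for i, t in enumerate(named):
        conc[t] = 0.9 * 0.90 ** i
    for i, t in enumerate(shared_filler):
        conc[t] = 0.30 * 0.85 ** i
    for i, t in enumerate(filler):
        conc[t] = 0.30 * 0.93 ** i
    for t in rare:
        conc[t] = 0.35
    return tuple(conc), conc, rare


def preset(name: str) -> CohortSpec:
    """Named cohort specifications.

    ``gut-paper`` / ``oral-paper`` / ``study`` all return the full paired
    design (83 subjects, mean depth 66,902, three community types per site
    built around the study's driver genera, four coupled core taxa); the
    site in the name only signals which side a caller intends to type.
    ``null-single-component`` collapses each site to a single component with
    no driver boosts and no coupling — the no-clustering null.
    """
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")

    _, gut_conc, rare = _panel("gut")
    _, oral_conc, _ = _panel("oral")

    if name == "null-single-component":
        gut_comps = (ComponentSpec(1.0, gut_conc),)
        oral_comps = (ComponentSpec(1.0, oral_conc),)
        coupled: dict[str, float] = {}
    else:
        gut_comps = tuple(
            ComponentSpec(w, gut_conc, driver_taxa=(d,))
            for w, d in zip((0.34, 0.33, 0.33), _GUT_DRIVERS))
        oral_comps = tuple(
            ComponentSpec(w, oral_conc, driver_taxa=(d,))
            for w, d in zip((0.34, 0.33, 0.33), _ORAL_DRIVERS))
        coupled = {t: _COUPLED_SIGMA for t in _SHARED_CORE[:4]}

    return CohortSpec(
        n_subjects=83,
        gut_components=gut_comps,
        oral_components=oral_comps,
        depth_mean=66902.0,
        depth_dispersion=10.0,
        coupled_taxa=coupled,
        core_block=_SHARED_CORE,
        rare_block=rare,
        rare_presence=0.15,
        seed=0,
    )


# ---------------------------------------------------------------------------
# pathway reference
# ---------------------------------------------------------------------------

def generate_pathway_reference(n_taxa: int, n_pathways: int,
                               sparsity: float = 0.5, seed: int = 0,
                               taxon_ids: Sequence[str] | None = None,
                               pathway_ids: Sequence[str] | None = None,
                               ) -> GeneCopyReference:
    """Random taxa x pathways gene-copy matrix.

    Each entry is zero with probability ``sparsity`` and otherwise a
    positive integer copy number (1 + Poisson(2)); deterministic under
    ``seed``.
    """
    if n_taxa < 1 or n_pathways < 1:
        raise ValueError("n_taxa and n_pathways must be positive")
    if not 0 <= sparsity < 1:
        raise ValueError("sparsity must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    present = rng.random((n_taxa, n_pathways)) >= sparsity
    copies = present * (1 + rng.poisson(2.0, size=(n_taxa, n_pathways)))
    taxon_ids = tuple(taxon_ids) if taxon_ids is not None else \
        tuple(f"taxon_{i + 1:03d}" for i in range(n_taxa))
    pathway_ids = tuple(pathway_ids) if pathway_ids is not None else \
        tuple(f"pwy_{j + 1:03d}" for j in range(n_pathways))
    if len(taxon_ids) != n_taxa or len(pathway_ids) != n_pathways:
        raise ValueError("id lists must match the requested shape")
    return GeneCopyReference(taxon_ids, pathway_ids,
                             copies.astype(float))


_KEGG_CLASSES = (
    "Metabolism", "Genetic Information Processing",
    "Environmental Information Processing", "Cellular Processes",
    "Organismal Systems",
)


def default_pathway_reference(taxon_ids: Sequence[str], n_pathways: int = 40,
                              sparsity: float = 0.5, seed: int = 0,
                              ) -> GeneCopyReference:
    """Reference covering ``taxon_ids`` with KEGG-style class labels."""
    ref = generate_pathway_reference(len(taxon_ids), n_pathways,
                                     sparsity=sparsity, seed=seed,
                                     taxon_ids=taxon_ids)
    category = {p: _KEGG_CLASSES[j % len(_KEGG_CLASSES)]
                for j, p in enumerate(ref.pathway_ids)}
    return replace(ref, category=category)
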