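"""Synthetic data generators with ground truth for every pipeline stage.

Three generators emulate the statistical structure of the study data:

* ``simulate_plate`` — sigmoidal A600 growth curves with baseline noise and
  optional single-reading bubble artifacts, in 96-well-array layout
  (duplicate substrate wells plus no-carbohydrate negative controls,
  readings every 15 min for 4 days);
* ``simulate_phenotype_panel`` — a strains x substrates phenotype matrix
  with species-level archetypes, strain-level trait dropout and noise,
  realizable as logistic plate curves;
* ``simulate_pangenome_pair`` — a two-species pangenome of conserved
  single-copy core "nodes" with species-biased accessory segments in the
  inter-node intervals, core genes evolved under Jukes-Cantor on a clock
  tree (within-species expectation d_w = 0.03, between-species d_b = 0.25,
  straddling the 0.1 transfer threshold), and injected interspecies transfer
  events recorded as ground truth.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .growth import NEGATIVE_CONTROL, KineticCurve, PhenotypeMatrix
from .pangenome import PUL, AnnotatedGenome, Gene

import pandas as pd

__all__ = [
    "PlateSpec",
    "PangenomeSpec",
    "curve_census",
    "simulate_plate",
    "simulate_phenotype_panel",
    "simulate_pangenome_pair",
    "simulate_expression",
]

DNA = np.frombuffer(b"ACGT", dtype="S1")
AA = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype="S1")


def curve_census(n_strains: int = 354, n_substrates: int = 45, replicates: int = 2) -> int:
    """Number of individual growth curves in a full array campaign."""
    return n_strains * n_substrates * replicates


@dataclass
class PlateSpec:
    """Layout and curve parameters for one simulated array campaign.

    ``curve_params`` maps (strain, substrate) to logistic parameters
    (baseline, plateau, rate /min, lag min); negative-control wells are
    generated automatically with plateau = baseline.
    """

    strains: list[str]
    substrates: list[str]
    replicates: int = 2
    timestep: float = 15.0
    duration: float = 5760.0  # 4 days
    curve_params: dict[tuple[str, str], tuple[float, float, float, float]] = field(
        default_factory=dict
    )
    n_controls: int = 2
    noise_sd: float = 0.01
    artifact_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        problems = []
        if self.duration / self.timestep < 50:
            problems.append("duration/timestep must be >= 50 points")
        if self.replicates < 1:
            problems.append("replicates must be >= 1")
        if self.noise_sd < 0 or self.artifact_rate < 0:
            problems.append("noise_sd and artifact_rate must be >= 0")
        for key, (baseline, plateau, rate, lag) in self.curve_params.items():
            if plateau < baseline:
                problems.append(f"{key}: plateau < baseline")
            if rate <= 0 or lag < 0 or baseline < 0:
                problems.append(f"{key}: bad logistic parameters")
        if problems:
            raise ValueError("invalid PlateSpec: " + "; ".join(problems))

    def census(self) -> int:
        return curve_census(len(self.strains), len(self.substrates), self.replicates)


def _logistic(t: np.ndarray, baseline: float, plateau: float, rate: float, lag: float) -> np.ndarray:
    return baseline + (plateau - baseline) / (1.0 + np.exp(-rate * (t - lag)))


def simulate_plate(spec: PlateSpec) -> tuple[list[KineticCurve], dict[str, dict]]:
    """Generate kinetic curves for every well of the array, with truth.

    Returns (curves, truth) where truth maps well_id to the generating
    parameters and the true total growth (plateau - baseline).
    """
    rng = np.random.default_rng(spec.seed)
    t = np.arange(0.0, spec.duration + spec.timestep / 2, spec.timestep)
    curves: list[KineticCurve] = []
    truth: dict[str, dict] = {}
    for strain in spec.strains:
        layout = [(sub, rep) for sub in spec.substrates for rep in range(1, spec.replicates + 1)]
        layout += [(NEGATIVE_CONTROL, rep) for rep in range(1, spec.n_controls + 1)]
        for sub, rep in layout:
            if sub == NEGATIVE_CONTROL:
                baseline, plateau, rate, lag = 0.1, 0.1, 0.01, 1000.0
            else:
                baseline, plateau, rate, lag = spec.curve_params.get(
                    (strain, sub), (0.1, 0.1, 0.01, 1000.0)
                )
            a = _logistic(t, baseline, plateau, rate, lag)
            if spec.noise_sd > 0:
                a = a + rng.normal(0.0, spec.noise_sd, size=t.shape)
            if spec.artifact_rate > 0:
                spikes = rng.random(t.shape) < spec.artifact_rate
                a = a + spikes * rng.uniform(0.3, 0.6, size=t.shape)
            a = np.clip(a, 0.0, None)
            well_id = f"{strain}:{sub}:r{rep}"
            curves.append(
                KineticCurve(
                    well_id=well_id,
                    strain_id=strain,
                    substrate_id=sub,
                    replicate=rep,
                    times=t,
                    a600=a,
                )
            )
            truth[well_id] = {
                "baseline": baseline,
                "plateau": plateau,
                "rate": rate,
                "lag": lag,
                "true_total_growth": plateau - baseline,
            }
    return curves, truth


def simulate_phenotype_panel(
    n_species: int = 4,
    strains_per_species: int = 5,
    archetypes: np.ndarray | None = None,
    trait_dropout_p: float = 0.0,
    noise_sd: float = 0.0,
    n_substrates: int = 30,
    seed: int = 0,
) -> tuple[PhenotypeMatrix, dict[str, str], PlateSpec]:
    """Strain phenotype matrix built from species archetypes.

    Each strain's value on a substrate is its species archetype, zeroed with
    probability ``trait_dropout_p`` (strain-level trait loss) and perturbed
    by Gaussian noise, clipped to [0, 1].  Returns the truth matrix (called
    stage), the strain -> species map, and a PlateSpec realizing the values
    as logistic plateau gains above a 0.1 baseline.
    """
    rng = np.random.default_rng(seed)
    if archetypes is None:
        present = rng.random((n_species, n_substrates)) > 0.45
        archetypes = present * rng.uniform(0.2, 1.0, size=(n_species, n_substrates))
    else:
        archetypes = np.asarray(archetypes, dtype=float)
        if np.any(archetypes < 0) or np.any(archetypes > 1):
            raise ValueError("archetype values must lie in [0, 1]")
        n_species, n_substrates = archetypes.shape
    substrates = [f"S{j + 1:02d}" for j in range(n_substrates)]
    strains, species_map, rows = [], {}, []
    for si in range(n_species):
        sp = f"species{si + 1}"
        for k in range(strains_per_species):
            strain = f"{sp}_st{k + 1}"
            strains.append(strain)
            species_map[strain] = sp
            keep = rng.random(n_substrates) >= trait_dropout_p
            vals = archetypes[si] * keep
            if noise_sd > 0:
                vals = vals + rng.normal(0.0, noise_sd, size=n_substrates)
            rows.append(np.clip(vals, 0.0, 1.0))
    values = pd.DataFrame(np.array(rows), index=strains, columns=substrates)
    # realized growth rate proportional to level; same block structure
    truth = PhenotypeMatrix(
        growth=values,
        rate=values * 1e-3,
        stage="called",
        is_growth=values > 0.1,
    )
    params = {
        (strain, sub): (0.1, 0.1 + float(values.loc[strain, sub]), 0.01, float(rng.uniform(600, 1500)))
        for strain in strains
        for sub in substrates
    }
    spec = PlateSpec(strains=strains, substrates=substrates, curve_params=params, seed=seed)
    return truth, species_map, spec


@dataclass
class PangenomeSpec:
    """Parameters of the synthetic two-species pangenome.

    ``d_w`` / ``d_b`` are expected pairwise nucleotide distances
    (substitutions/site) within and between species; the invariant
    d_w < 0.1 < d_b guarantees the transfer threshold separates the species
    by construction.  Protein sequences evolve on the same tree with branch
    lengths scaled by ``protein_scale`` (purifying selection), keeping
    cross-species orthologs above the 90% amino acid family cutoff.
    """

    genomes_per_species: int = 5
    n_core: int = 200
    accessory_pool: int = 900
    p_insert: float = 0.3
    sequence_length: int = 900
    d_w: float = 0.03
    d_b: float = 0.25
    n_transfers: int = 10
    span: int = 2
    protein_scale: float = 0.2
    pul_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        problems = []
        if not (self.d_w < 0.1 < self.d_b):
            problems.append("d_w < 0.1 < d_b required")
        if self.n_transfers * self.span > self.n_core:
            problems.append("n_transfers * span exceeds n_core")
        if self.genomes_per_species < 2:
            problems.append("need >= 2 genomes per species")
        if self.sequence_length < 30 or self.sequence_length % 3:
            problems.append("sequence_length must be a multiple of 3, >= 30")
        if problems:
            raise ValueError("invalid PangenomeSpec: " + "; ".join(problems))


def _evolve_dna(seq: np.ndarray, d: float, rng: np.random.Generator) -> np.ndarray:
    """One JC branch: per-site substitution probability 3/4 (1 - e^{-4d/3})."""
    p = 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))
    out = seq.copy()
    hit = rng.random(seq.shape) < p
    shift = rng.integers(1, 4, size=int(hit.sum()))
    out[hit] = (out[hit] + shift) % 4
    return out


def _evolve_protein(seq: np.ndarray, d: float, rng: np.random.Generator) -> np.ndarray:
    """20-state analogue of the JC branch process."""
    p = (19.0 / 20.0) * (1.0 - np.exp(-20.0 * d / 19.0))
    out = seq.copy()
    hit = rng.random(seq.shape) < p
    shift = rng.integers(1, 20, size=int(hit.sum()))
    out[hit] = (out[hit] + shift) % 20
    return out


def _dna_str(codes: np.ndarray) -> str:
    return DNA[codes].tobytes().decode()


def _aa_str(codes: np.ndarray) -> str:
    return AA[codes].tobytes().decode()


def _segment_labels(rng: np.random.Generator, as_pul: bool) -> list[str]:
    caz = [f"{fam}{rng.integers(1, 100)}" for fam in ("GH", "PL", "CE")]
    if as_pul:
        n_extra = int(rng.integers(1, 4))
        extras = list(
            rng.choice(
                np.array([caz[0], caz[1], "sulfatase", "regulator", "other"], dtype=object),
                size=n_extra,
            )
        )
        return ["susC", "susD", f"GH{rng.integers(1, 100)}"] + extras
    n = int(rng.integers(1, 5))
    return list(
        rng.choice(np.array(["other", "other", "other", "regulator", caz[2]], dtype=object), size=n)
    )


def simulate_pangenome_pair(
    spec: PangenomeSpec,
) -> tuple[list[AnnotatedGenome], dict, dict]:
    """Generate a two-species pangenome with injected interspecies transfers.

    Core "node" families occur single-copy in the same order in every genome;
    accessory segments (about ``pul_fraction`` of them valid PUL cassettes)
    are species-specific and sit in inter-node intervals.  Each transfer
    event copies a donor genome's run of ``span`` consecutive node alleles,
    and the intervening accessory content, verbatim into a recipient genome
    of the other species (homologous recombination replaces, does not
    mutate).  Transfer sites are chosen where the donor species carries
    accessory content, so every event moves accessory genes.

    Returns (genomes, families, truth): ``families`` holds the ground-truth
    gene -> family map, node order, and species map; ``truth`` the injected
    (genome, core family) allele replacements, transferred accessory
    families, and recipient species per event.
    """
    rng = np.random.default_rng(spec.seed)
    n_per = spec.genomes_per_species
    species = ("speciesA", "speciesB")
    genome_ids = [f"{sp}_g{k + 1}" for sp in species for k in range(n_per)]
    species_map = {g: ("speciesA" if g.startswith("speciesA") else "speciesB") for g in genome_ids}

    L = spec.sequence_length
    Lp = L // 3
    branch_anc = (spec.d_b - spec.d_w) / 2.0
    branch_leaf = spec.d_w / 2.0

    node_fams = [f"NODE{i:04d}" for i in range(spec.n_core)]
    # core alleles: dna[fam][genome], protein[fam][genome]
    core_dna: dict[str, dict[str, np.ndarray]] = {}
    core_prot: dict[str, dict[str, np.ndarray]] = {}
    for fam in node_fams:
        root_d = rng.integers(0, 4, size=L)
        root_p = rng.integers(0, 20, size=Lp)
        anc_d = {sp: _evolve_dna(root_d, branch_anc, rng) for sp in species}
        anc_p = {sp: _evolve_protein(root_p, branch_anc * spec.protein_scale, rng) for sp in species}
        core_dna[fam] = {}
        core_prot[fam] = {}
        for g in genome_ids:
            sp = species_map[g]
            core_dna[fam][g] = _evolve_dna(anc_d[sp], branch_leaf, rng)
            core_prot[fam][g] = _evolve_protein(anc_p[sp], branch_leaf * spec.protein_scale, rng)

    # species-level accessory segments per internal inter-node interval
    acc_counter = 0
    acc_prot: dict[str, np.ndarray] = {}
    acc_dna: dict[str, np.ndarray] = {}
    acc_label: dict[str, str] = {}
    segments: dict[tuple[int, str], list[str]] = {}  # (interval index, species) -> family ids
    for i in range(spec.n_core - 1):
        for sp in species:
            if rng.random() >= spec.p_insert:
                continue
            labels = _segment_labels(rng, as_pul=rng.random() < spec.pul_fraction)
            fams = []
            for lab in labels:
                if acc_counter >= spec.accessory_pool:
                    raise ValueError("accessory pool exhausted; raise accessory_pool")
                fam = f"ACC{acc_counter:04d}"
                acc_counter += 1
                acc_prot[fam] = rng.integers(0, 20, size=Lp)
                acc_dna[fam] = rng.integers(0, 4, size=L)
                acc_label[fam] = str(lab)
                fams.append(fam)
            segments[(i, sp)] = fams

    # per-genome content: node i, then interval i content
    content: dict[str, list[tuple[str, str]]] = {}  # genome -> [(family, kind)]
    for g in genome_ids:
        sp = species_map[g]
        items: list[tuple[str, str]] = []
        for i, fam in enumerate(node_fams):
            items.append((fam, "core"))
            if i < spec.n_core - 1:
                for acc in segments.get((i, sp), []):
                    items.append((acc, "acc"))
        content[g] = items

    # choose non-adjacent transfer runs whose interior intervals carry donor content
    donors_species = [species[int(rng.integers(0, 2))] for _ in range(spec.n_transfers)]
    used: set[int] = set()
    events = []
    order = rng.permutation(spec.n_core - spec.span + 1)
    ei = 0
    for start in order:
        if ei >= spec.n_transfers:
            break
        start = int(start)
        run = range(start, start + spec.span)
        # keep runs separated so loci stay distinct
        if any((r in used) or (r - 1 in used) or (r + 1 in used) for r in run):
            continue
        donor_sp = donors_species[ei]
        interior = [i for i in range(start, start + spec.span - 1)]
        if interior and not any(segments.get((i, donor_sp)) for i in interior):
            continue
        if not interior and not (
            segments.get((start - 1, donor_sp)) or segments.get((start, donor_sp))
        ):
            continue
        used.update(run)
        recip_sp = species[0] if donor_sp == species[1] else species[1]
        donor = f"{donor_sp}_g{int(rng.integers(1, n_per + 1))}"
        recipient = f"{recip_sp}_g{int(rng.integers(1, n_per + 1))}"
        events.append({"nodes": [node_fams[r] for r in run], "interior_intervals": interior,
                       "donor": donor, "recipient": recipient, "recipient_species": recip_sp})
        ei += 1
    if len(events) < spec.n_transfers:
        raise ValueError("could not place all transfer events; lower n_transfers or raise p_insert")

    transferred_alleles: set[tuple[str, str]] = set()
    transferred_accessory: set[str] = set()
    for ev in events:
        donor, recipient = ev["donor"], ev["recipient"]
        donor_sp = species_map[donor]
        for fam in ev["nodes"]:
            core_dna[fam][recipient] = core_dna[fam][donor].copy()
            core_prot[fam][recipient] = core_prot[fam][donor].copy()
            transferred_alleles.add((recipient, fam))
        # replace interior interval content with the donor's
        new_items: list[tuple[str, str]] = []
        interior = set(ev["interior_intervals"])
        i = -1
        for fam, kind in content[recipient]:
            if kind == "core":
                i += 1
                new_items.append((fam, kind))
            elif i in interior:
                continue  # drop recipient's own content here
            else:
                new_items.append((fam, kind))
        # insert donor content after each interior node
        rebuilt: list[tuple[str, str]] = []
        i = -1
        for fam, kind in new_items:
            rebuilt.append((fam, kind))
            if kind == "core":
                i += 1
                if i in interior:
                    for acc in segments.get((i, donor_sp), []):
                        rebuilt.append((acc, "acc"))
                        transferred_accessory.add(acc)
        content[recipient] = rebuilt

    genomes: list[AnnotatedGenome] = []
    gene_to_family: dict[tuple[str, str], str] = {}
    for g in genome_ids:
        genes: list[Gene] = []
        pos = 1
        for idx, (fam, kind) in enumerate(content[g]):
            if kind == "core":
                dna = _dna_str(core_dna[fam][g])
                prot = _aa_str(core_prot[fam][g])
                labels = frozenset({"other"})
            else:
                dna = _dna_str(acc_dna[fam])
                prot = _aa_str(acc_prot[fam])
                labels = frozenset({acc_label[fam]})
            gene_id = f"{g}_{idx + 1:05d}"
            genes.append(
                Gene(
                    gene_id=gene_id,
                    contig=f"{g}_c1",
                    start=pos,
                    end=pos + len(dna) - 1,
                    strand="+",
                    protein=prot,
                    labels=labels,
                    dna=dna,
                )
            )
            gene_to_family[(g, gene_id)] = fam
            pos += len(dna) + 100
        genomes.append(AnnotatedGenome(genome_id=g, species_id=species_map[g], genes=genes))

    families = {
        "gene_to_family": gene_to_family,
        "core_families": node_fams,
        "accessory_families": sorted(acc_prot),
        "species_map": species_map,
    }
    truth = {
        "transferred_alleles": transferred_alleles,
        "transferred_accessory": transferred_accessory,
        "events": events,
    }
    return genomes, families, truth


def simulate_expression(
    puls: list[PUL],
    activated_pul_ids: list[str],
    fold_range: tuple[float, float] = (10.5, 50.0),
    background_range: tuple[float, float] = (0.2, 5.0),
    threshold: float = 10.0,
    seed: int = 0,
) -> dict[str, float]:
    """Fold-change table: genes of activated PULs draw from ``fold_range``,
    all other PUL genes from ``background_range``."""
    ids = {p.pul_id for p in puls}
    unknown = set(activated_pul_ids) - ids
    if unknown:
        raise ValueError(f"unknown PUL ids: {sorted(unknown)}")
    if fold_range[0] <= threshold or background_range[1] > threshold:
        warnings.warn(
            "fold-change ranges straddle the activation threshold; "
            "round-trip recovery is not guaranteed (the rule is strict)"
        )
    rng = np.random.default_rng(seed)
    table: dict[str, float] = {}
    activated = set(activated_pul_ids)
    for p in puls:
        lo, hi = fold_range if p.pul_id in activated else background_range
        for gid in p.gene_ids:
            table[gid] = float(rng.uniform(lo, hi))
    return table
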