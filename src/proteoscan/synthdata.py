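"""Synthetic knockout-screen generator.

Emulates the statistical structure of a multiplexed TMT knockout screen so
the whole analysis pipeline can be exercised without the deposited data:

* 10plex run layout — up to eight knockouts per run plus a technical
  spike-in (127C, one frozen wild-type lysate shared by all runs) and a
  biological wild-type control (130N) grown alongside the knockouts;
* per-(protein, run) and per-(protein, plate) batch shifts — samples grown
  on the same plate and measured in the same run are more alike;
* abundance-dependent (MNAR) missingness — abundant proteins are
  quantified more often, via a logistic link on base abundance;
* sparse knockout effects, additive on the log2 scale;
* co-expression modules — groups of proteins sharing a latent per-sample
  factor, the structure the SOM clustering stage recovers;
* growth (OD600) negatively coupled to the extent of proteome remodeling
  beyond a knee.

The companion paired-omics generator produces matched transcript/protein
replicate matrices in which a configurable subset of genes is regulated
only translationally (protein change at stable mRNA), in two archetypes
(mostly-up and mostly-down across strains); the ORF generator then plants
a codon-optimality signal in those classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil, comb

import numpy as np
import pandas as pd

from .datamodel import (
    ALL_CODONS,
    BIOLOGICAL_CHANNEL,
    TECHNICAL_CHANNEL,
    TMT10_CHANNELS,
    AnnotationNetwork,
    CodonTable,
    GrowthTable,
    IntensityMatrix,
    ORFSet,
    SampleManifest,
    TranscriptMatrix,
    ValidationError,
)

_KO_CHANNELS = tuple(
    c for c in TMT10_CHANNELS if c not in (TECHNICAL_CHANNEL, BIOLOGICAL_CHANNEL)
)

_WELLS = tuple(f"{r}{c}" for r in "ABCDEFGH" for c in range(1, 13))


@dataclass
class ScreenSimConfig:
    """Conditions for one simulated screen.

    Defaults are a desk-scale screen (800 proteins, 120 knockouts, 24 WT
    biological replicates over 24 runs on 2 plates) preserving the full
    design structure.  Abundances are log2 reporter intensities.
    """

    n_proteins: int = 800
    n_knockouts: int = 120
    n_wt_bio: int = 24
    runs_per_plate: int = 12
    seed: int = 0
    base_abundance_mean: float = 20.0
    base_abundance_sd: float = 2.0
    run_batch_sd: float = 0.5
    plate_batch_sd: float = 0.3
    noise_sd: float = 0.25
    #: logit of missingness vs standardized base abundance
    missing_slope: float = -1.5
    missing_intercept: float = -2.2
    #: mean fraction of proteins altered per knockout strain
    effect_fraction: float = 0.05
    #: lognormal sigma of the per-strain altered fraction (0 = constant);
    #: knockout libraries show heavy-tailed remodeling extents, from strains
    #: with no proteome change to strains remodeling hundreds of proteins
    effect_dispersion: float = 1.0
    #: SD of true effect sizes, in units of the wild-type biological SD
    effect_sd: float = 6.0
    n_modules: int = 10
    module_loading_sd: float = 0.5
    growth_baseline: float = 1.2
    growth_noise_sd: float = 0.05
    growth_knee: int = 30
    growth_decline: float = 0.02

    def validate(self) -> None:
        sds = dict(base_abundance_sd=self.base_abundance_sd,
                   run_batch_sd=self.run_batch_sd,
                   plate_batch_sd=self.plate_batch_sd,
                   noise_sd=self.noise_sd, effect_sd=self.effect_sd,
                   module_loading_sd=self.module_loading_sd,
                   growth_noise_sd=self.growth_noise_sd)
        bad = [k for k, v in sds.items() if v < 0]
        if bad:
            raise ValidationError(f"negative SDs: {bad}")
        if not 0.0 <= self.effect_fraction <= 1.0:
            raise ValidationError("effect_fraction must lie in [0, 1]")
        if self.n_knockouts > 8 * self.n_wt_bio:
            raise ValidationError(
                "need n_wt_bio >= ceil(n_knockouts / 8): one run per "
                "biological control, at most 8 knockouts per run"
            )
        for k in ("n_proteins", "n_knockouts", "n_wt_bio", "runs_per_plate"):
            if getattr(self, k) < 1:
                raise ValidationError(f"{k} must be positive")


@dataclass
class SimTruth:
    """Ground truth accompanying a generated dataset."""

    effects: pd.DataFrame | None = None        # proteins × KO strains, true log2 effects
    modules: pd.Series | None = None           # protein → module id
    regulation_class: pd.Series | None = None  # gene → up_translational | down_translational | transcriptional | null
    transcript_fc: pd.DataFrame | None = None  # genes × strains, true transcript log2FC
    protein_fc: pd.DataFrame | None = None     # genes × strains, true protein log2FC
    sample_to_strain: pd.DataFrame | None = None  # sample_id, strain_id, layer


def build_layout(
    n_knockouts: int,
    n_wt_bio: int,
    runs_per_plate: int = 12,
    strain_ids: list[str] | None = None,
) -> SampleManifest:
    """Deterministic run layout: one run per biological control.

    Knockouts are distributed at most 8 per run; every run receives one
    technical (127C) and one biological (130N) wild-type control.  With the
    full-scale numbers (3308 knockouts, 461 controls) this reproduces the
    screen's 3769-sample arithmetic.
    """
    if n_knockouts > 8 * n_wt_bio:
        raise ValidationError("too many knockouts for the number of runs")
    if strain_ids is None:
        width = max(4, len(str(n_knockouts)))
        strain_ids = [f"ko{i:0{width}d}" for i in range(n_knockouts)]
    n_runs = n_wt_bio
    per_run = [len(chunk) for chunk in np.array_split(np.arange(n_knockouts), n_runs)]
    records = []
    pos = 0
    well_counter = 0
    for r, n_ko in enumerate(per_run):
        run = f"run{r:04d}"
        plate = f"plate{r // runs_per_plate:03d}"
        for k in range(n_ko):
            records.append(dict(
                sample_id=f"s_{strain_ids[pos]}", strain_id=strain_ids[pos],
                sample_type="knockout", plate_id=plate,
                well=_WELLS[well_counter % 96], run_id=run,
                channel=_KO_CHANNELS[k],
            ))
            pos += 1
            well_counter += 1
        records.append(dict(
            sample_id=f"s_wtbio_{r:04d}", strain_id="WT",
            sample_type="wt_biological", plate_id=plate,
            well=_WELLS[well_counter % 96], run_id=run,
            channel=BIOLOGICAL_CHANNEL,
        ))
        well_counter += 1
        records.append(dict(
            sample_id=f"s_wttech_{r:04d}", strain_id="WT",
            sample_type="wt_technical", plate_id=plate,
            well="A1", run_id=run, channel=TECHNICAL_CHANNEL,
        ))
    return SampleManifest(pd.DataFrame(records))


def generate_screen(
    config: ScreenSimConfig,
) -> tuple[IntensityMatrix, SampleManifest, GrowthTable, SimTruth]:
    """Simulate one full screen.

    Protein log2 intensity is ``base + loading · module factor + knockout
    effect + run shift + plate shift + noise``; the technical spike-in is
    the frozen base profile plus run shift and measurement noise (it was
    never grown on a plate, so it carries no plate shift).  Wild-type
    samples carry zero knockout effect.  Returned intensities are on the
    raw scale (2**log2), zeros/missing encoded as NaN.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    c = config

    manifest = build_layout(c.n_knockouts, c.n_wt_bio, c.runs_per_plate)
    mdf = manifest.frame
    proteins = [f"prot{i:04d}" for i in range(c.n_proteins)]
    ko_strains = [s for s in mdf.loc[mdf.sample_type == "knockout", "strain_id"]]

    modules = pd.Series(np.arange(c.n_proteins) % c.n_modules, index=proteins,
                        name="module")
    base = rng.normal(c.base_abundance_mean, c.base_abundance_sd, c.n_proteins)

    runs = mdf["run_id"].drop_duplicates().tolist()
    plates = mdf["plate_id"].drop_duplicates().tolist()
    run_shift = {r: rng.normal(0, c.run_batch_sd, c.n_proteins) for r in runs}
    plate_shift = {p: rng.normal(0, c.plate_batch_sd, c.n_proteins) for p in plates}

    # wild-type biological SD (post-normalization residual): module factor + noise
    wt_sd = float(np.hypot(c.module_loading_sd, c.noise_sd))
    effects = pd.DataFrame(0.0, index=proteins, columns=ko_strains)
    # heavy-tailed per-strain remodeling extent (mean-one lognormal factor)
    disp = c.effect_dispersion
    factors = (np.exp(rng.normal(-0.5 * disp**2, disp, len(ko_strains)))
               if disp > 0 else np.ones(len(ko_strains)))
    for s, fct in zip(ko_strains, factors):
        frac = min(1.0, c.effect_fraction * fct)
        hit = rng.random(c.n_proteins) < frac
        eff = np.zeros(c.n_proteins)
        eff[hit] = rng.normal(0.0, c.effect_sd * wt_sd, int(hit.sum()))
        effects[s] = eff

    module_idx = modules.to_numpy()
    cols: dict[str, np.ndarray] = {}
    for row in mdf.itertuples(index=False):
        x = base.copy()
        x += run_shift[row.run_id]
        if row.sample_type == "wt_technical":
            x += rng.normal(0, c.noise_sd, c.n_proteins)
        else:
            factors = rng.normal(0, 1.0, c.n_modules)
            x += c.module_loading_sd * factors[module_idx]
            x += plate_shift[row.plate_id]
            if row.sample_type == "knockout":
                x += effects[row.strain_id].to_numpy()
            x += rng.normal(0, c.noise_sd, c.n_proteins)
        cols[row.sample_id] = x

    log2 = pd.DataFrame(cols, index=proteins)

    # MNAR missingness: logistic in standardized base abundance
    z_abund = (base - c.base_abundance_mean) / max(c.base_abundance_sd, 1e-12)
    p_miss = 1.0 / (1.0 + np.exp(-(c.missing_intercept + c.missing_slope * z_abund)))
    miss = rng.random(log2.shape) < p_miss[:, None]
    raw = pd.DataFrame(np.where(miss, np.nan, 2.0 ** log2.to_numpy()),
                       index=proteins, columns=log2.columns)

    altered_count = (effects != 0.0).sum(axis=0)
    plate_of_strain = (
        mdf[mdf.sample_type == "knockout"].set_index("strain_id")["plate_id"]
    )
    od = (
        c.growth_baseline
        + rng.normal(0, c.growth_noise_sd, len(ko_strains))
        - c.growth_decline * np.maximum(0, altered_count.to_numpy() - c.growth_knee)
    )
    od = np.maximum(od, 0.05)  # OD600 cannot go negative
    growth = GrowthTable(pd.DataFrame(dict(
        strain_id=ko_strains,
        plate_id=plate_of_strain.reindex(ko_strains).to_numpy(),
        od600=od,
    )))

    truth = SimTruth(effects=effects, modules=modules)
    return IntensityMatrix(raw, scale="raw"), manifest, growth, truth


# -- paired transcriptome / proteome ------------------------------------------

@dataclass
class PairedSimConfig:
    """Conditions for the paired transcriptome–proteome experiment.

    Defaults mirror a 94-strain quadruplicate follow-up on ~1700 genes with
    roughly 1200 genes regulated only at the protein level (two archetypes,
    mostly-up and mostly-down across strains) so that the protein-only
    selection keeps on the order of 750 genes.
    """

    n_genes: int = 1706
    n_strains: int = 94
    n_replicates: int = 4
    seed: int = 0
    n_up: int = 600
    n_down: int = 600
    n_transcriptional: int = 306
    base_log2_cpm_mean: float = 7.0
    base_log2_cpm_sd: float = 2.0
    base_log2_protein_mean: float = 20.0
    base_log2_protein_sd: float = 2.0
    replicate_noise_sd: float = 0.25
    #: translational archetype: gene amplitude ~ N(1, amp_sd), strain multiplier ~ N(1, strain_sd)
    translational_amp_sd: float = 0.2
    translational_strain_sd: float = 0.3
    translational_scale: float = 1.0
    #: transcriptional genes: per (gene, strain) active with this probability
    transcriptional_active_fraction: float = 0.15
    transcriptional_fc_sd: float = 1.2

    def validate(self) -> None:
        if self.n_up + self.n_down + self.n_transcriptional > self.n_genes:
            raise ValidationError("regulation class counts exceed n_genes")
        if self.n_replicates < 2:
            raise ValidationError("need at least 2 replicates per strain")
        for k in ("replicate_noise_sd", "translational_amp_sd",
                  "translational_strain_sd", "transcriptional_fc_sd"):
            if getattr(self, k) < 0:
                raise ValidationError(f"{k} must be non-negative")
        if not 0 <= self.transcriptional_active_fraction <= 1:
            raise ValidationError("transcriptional_active_fraction must lie in [0,1]")


def generate_paired_omics(
    config: PairedSimConfig,
) -> tuple[TranscriptMatrix, IntensityMatrix, SimTruth]:
    """Matched transcript / protein replicate matrices for selected strains.

    Per gene and strain, protein log2FC = transcript log2FC + translational
    log2FC.  Translational-only genes have transcript FC identically zero
    and follow one of two archetypes: mostly-up or mostly-down across
    strains.  Transcriptional genes propagate their transcript FC to the
    protein layer.  Both matrices carry ``n_replicates`` columns per strain
    plus wild-type replicates; the sample ↔ strain map travels in the
    returned truth object.
    """
    config.validate()
    c = config
    rng = np.random.default_rng(c.seed)

    genes = [f"gene{i:04d}" for i in range(c.n_genes)]
    strains = [f"ko{i:03d}" for i in range(c.n_strains)]
    classes = np.array(
        ["up_translational"] * c.n_up
        + ["down_translational"] * c.n_down
        + ["transcriptional"] * c.n_transcriptional
        + ["null"] * (c.n_genes - c.n_up - c.n_down - c.n_transcriptional)
    )
    rng.shuffle(classes)
    reg_class = pd.Series(classes, index=genes, name="regulation_class")

    t_fc = pd.DataFrame(0.0, index=genes, columns=strains)
    p_fc = pd.DataFrame(0.0, index=genes, columns=strains)

    is_tr = classes == "transcriptional"
    n_tr = int(is_tr.sum())
    if n_tr:
        active = rng.random((n_tr, c.n_strains)) < c.transcriptional_active_fraction
        fc = np.where(active, rng.normal(0, c.transcriptional_fc_sd,
                                         (n_tr, c.n_strains)), 0.0)
        t_fc.loc[is_tr, :] = fc
        p_fc.loc[is_tr, :] = fc  # protein follows transcript

    strain_mult = rng.normal(1.0, c.translational_strain_sd, c.n_strains)
    for label, sign in (("up_translational", 1.0), ("down_translational", -1.0)):
        sel = classes == label
        n_sel = int(sel.sum())
        if n_sel:
            amp = rng.normal(1.0, c.translational_amp_sd, n_sel)
            p_fc.loc[sel, :] = sign * c.translational_scale * np.outer(amp, strain_mult)

    base_t = rng.normal(c.base_log2_cpm_mean, c.base_log2_cpm_sd, c.n_genes)
    base_p = rng.normal(c.base_log2_protein_mean, c.base_log2_protein_sd, c.n_genes)

    all_strains = strains + ["WT"]
    sample_rows = []
    t_cols: dict[str, np.ndarray] = {}
    p_cols: dict[str, np.ndarray] = {}
    for s in all_strains:
        tfc = t_fc[s].to_numpy() if s != "WT" else np.zeros(c.n_genes)
        pfc = p_fc[s].to_numpy() if s != "WT" else np.zeros(c.n_genes)
        for r in range(c.n_replicates):
            sid = f"{s}_r{r + 1}"
            t_cols[sid] = base_t + tfc + rng.normal(0, c.replicate_noise_sd, c.n_genes)
            p_cols[sid] = base_p + pfc + rng.normal(0, c.replicate_noise_sd, c.n_genes)
            sample_rows.append(dict(sample_id=sid, strain_id=s, replicate=r + 1))

    txome = TranscriptMatrix(pd.DataFrame(t_cols, index=genes))
    proteome = IntensityMatrix(pd.DataFrame(p_cols, index=genes), scale="log")
    truth = SimTruth(
        regulation_class=reg_class,
        transcript_fc=t_fc,
        protein_fc=p_fc,
        sample_to_strain=pd.DataFrame(sample_rows),
    )
    return txome, proteome, truth


# -- ORFs with a planted codon-optimality signal ------------------------------

def generate_orfs(
    truth: SimTruth,
    codon_table: CodonTable,
    bias: float = 1.0,
    codon_range: tuple[int, int] = (100, 300),
    seed: int = 0,
) -> ORFSet:
    """Synthesize frame-valid coding sequences per regulation class.

    For genes regulated translationally upward, synonymous codons are drawn
    with probability tilted toward optimal codons by a factor ``exp(bias)``
    within each amino-acid family; mostly-down genes are tilted away by
    ``exp(-bias)``; all other classes draw uniformly.  At ``bias = 0`` the
    classes are exchangeable.
    """
    if bias < 0:
        raise ValidationError("bias must be non-negative")
    if truth.regulation_class is None or len(truth.regulation_class) == 0:
        raise ValidationError("truth carries no regulation classes")
    from Bio.Data.CodonTable import standard_dna_table

    rng = np.random.default_rng(seed)
    fwd = standard_dna_table.forward_table
    families: dict[str, list[str]] = {}
    for codon in ALL_CODONS:
        aa = fwd.get(codon)
        if aa is not None:
            families.setdefault(aa, []).append(codon)
    aas = sorted(families)
    stops = sorted(set(ALL_CODONS) - set(fwd))
    optimal = set(codon_table.optimal_codons)

    def family_weights(tilt: float) -> dict[str, np.ndarray]:
        out = {}
        for aa in aas:
            w = np.array([np.exp(tilt) if c in optimal else 1.0
                          for c in families[aa]])
            out[aa] = w / w.sum()
        return out

    tilt_of = {"up_translational": bias, "down_translational": -bias,
               "transcriptional": 0.0, "null": 0.0}
    weights = {k: family_weights(v) for k, v in tilt_of.items()}

    lo, hi = codon_range
    sequences: dict[str, str] = {}
    for gene, cls in truth.regulation_class.items():
        n_codons = int(rng.integers(lo, hi + 1))
        aa_seq = rng.choice(aas, size=n_codons)
        w = weights[cls]
        body = [
            families[aa][rng.choice(len(families[aa]), p=w[aa])]
            for aa in aa_seq
        ]
        stop = stops[rng.choice(len(stops))]
        sequences[gene] = "ATG" + "".join(body) + stop
    return ORFSet(sequences)


# -- annotation network with planted enrichment --------------------------------

def generate_annotation_network(
    truth: SimTruth,
    within_module_rate: float = 0.2,
    background_rate: float = 0.1,
    seed: int = 0,
    decoy_rate: float = 0.005,
) -> AnnotationNetwork:
    """Association network enriched within true co-expression modules.

    A pair inside one true module is associated (score > 150) with
    probability ``within_module_rate``; any other pair with
    ``background_rate``.  A small ``decoy_rate`` adds sub-threshold edges
    (score ≤ 150) so the association threshold is exercised.
    """
    for name, r in (("within_module_rate", within_module_rate),
                    ("background_rate", background_rate),
                    ("decoy_rate", decoy_rate)):
        if not 0.0 <= r <= 1.0:
            raise ValidationError(f"{name} must lie in [0, 1]")
    if within_module_rate < background_rate:
        raise ValidationError("within_module_rate must be >= background_rate")
    if truth.modules is None:
        raise ValidationError("truth carries no module membership")
    rng = np.random.default_rng(seed)
    proteins = np.array(truth.modules.index)
    mods = truth.modules.to_numpy()
    n = len(proteins)
    iu, ju = np.triu_indices(n, k=1)
    same = mods[iu] == mods[ju]
    rate = np.where(same, within_module_rate, background_rate)
    u = rng.random(len(iu))
    assoc = u < rate
    decoy = (~assoc) & (rng.random(len(iu)) < decoy_rate)
    rows = []
    if assoc.any():
        scores = rng.integers(151, 1001, int(assoc.sum()))
        rows.append(pd.DataFrame(dict(
            protein_a=proteins[iu[assoc]], protein_b=proteins[ju[assoc]],
            combined_score=scores)))
    if decoy.any():
        scores = rng.integers(1, 151, int(decoy.sum()))
        rows.append(pd.DataFrame(dict(
            protein_a=proteins[iu[decoy]], protein_b=proteins[ju[decoy]],
            combined_score=scores)))
    edges = (pd.concat(rows, ignore_index=True) if rows
             else pd.DataFrame(columns=["protein_a", "protein_b", "combined_score"]))
    return AnnotationNetwork(edges)
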