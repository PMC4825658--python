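"""Synthetic pooled reporter-screen generator.

Simulates a barcoded knockout pool carrying a fluorescent pathway reporter:
per-mutant phenotype classes set class/condition-specific log-normal GFP
distributions; cells are sorted by fluorescence gates into five pools (two
uninduced, three induced); each sorted pool is regrown, PCR-amplified with
per-gene log-normal efficiency noise, and sequenced into barcode amplicon
reads (multiplex tag + priming site + barcode), with uniform substitution
errors.  A ground-truth table records each mutant's class and analytic
gate-capture probabilities for downstream recovery tests.

All randomness flows from a single integer seed through
:class:`numpy.random.Generator` instances; identical configuration gives
bit-identical output.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .barcode_io import (
    AmpliconLayout,
    BarcodeCatalog,
    CatalogEntry,
    ReadRecord,
    write_fastq,
)

UNINDUCED = "uninduced"
INDUCED = "induced"

GATE_NAMES = ("Un_Gfp_neg", "Un_Gfp_plus", "In_Gfp_neg", "In_Gfp_basal", "In_Gfp_plusplus")

_BASE_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)


class PhenotypeClass(enum.Enum):
    WT = "WT"
    GFP_NEG = "GFP_NEG"  # pathway-null: reporter dark in both conditions
    NON_INDUCER = "NON_INDUCER"  # normal basal level, no induction
    HIGH_BASAL = "HIGH_BASAL"  # elevated basal, normal induction
    HYPER_INDUCER = "HYPER_INDUCER"  # normal basal, super-induced
    LOW_BASAL = "LOW_BASAL"  # reduced basal, normal induction
    BIMODAL = "BIMODAL"  # switching: dark majority + expressing minority


@dataclass(frozen=True)
class GfpModel:
    """Per class x condition mixture of log10-fluorescence components.

    ``components[cls][condition]`` is a tuple of ``(weight, loc, scale)``
    normal components on the log10 axis (a log-normal mixture per cell).
    Single-component entries have weight 1.
    """

    components: dict[PhenotypeClass, dict[str, tuple[tuple[float, float, float], ...]]]

    def __post_init__(self) -> None:
        for cls, byc in self.components.items():
            for cond, comps in byc.items():
                total = sum(w for w, _, _ in comps)
                if not math.isclose(total, 1.0, abs_tol=1e-9):
                    raise ValueError(f"{cls}/{cond}: component weights must sum to 1")
                for w, _, scale in comps:
                    if scale <= 0:
                        raise ValueError(f"{cls}/{cond}: scale must be > 0")
                    if not (0 < w <= 1):
                        raise ValueError(f"{cls}/{cond}: weight must be in (0,1]")

    def mixture(self, cls: PhenotypeClass, condition: str):
        try:
            return self.components[cls][condition]
        except KeyError:
            raise KeyError(f"no GFP model for class {cls} under {condition!r}") from None

    def median(self, cls: PhenotypeClass, condition: str) -> float:
        """Median log10 fluorescence (dominant component's location)."""
        comps = self.mixture(cls, condition)
        return max(comps, key=lambda c: c[0])[1]

    def sample(self, cls: PhenotypeClass, condition: str, n: int, rng: np.random.Generator
               ) -> np.ndarray:
        comps = self.mixture(cls, condition)
        if len(comps) == 1:
            _, loc, scale = comps[0]
            return rng.normal(loc, scale, size=n)
        weights = np.array([w for w, _, _ in comps])
        which = rng.choice(len(comps), size=n, p=weights)
        out = np.empty(n)
        for i, (_, loc, scale) in enumerate(comps):
            mask = which == i
            out[mask] = rng.normal(loc, scale, size=int(mask.sum()))
        return out

    def gate_probability(self, cls: PhenotypeClass, condition: str,
                         lower: float, upper: float) -> float:
        """Analytic P(lower <= log10 GFP < upper) from the mixture CDF."""
        p = 0.0
        for w, loc, scale in self.mixture(cls, condition):
            p += w * (norm.cdf(upper, loc, scale) - norm.cdf(lower, loc, scale))
        return float(p)


# default log10 landmarks: dark reporter ~1.0, basal ~2.0, induced ~3.5
_DARK, _BASAL, _IND, _SCALE = 1.0, 2.0, 3.5, 0.15
_BIMODAL_MINOR_WEIGHT = 0.2


def default_gfp_models(
    *,
    dark_loc: float = _DARK,
    basal_loc: float = _BASAL,
    induced_loc: float = _IND,
    scale: float = _SCALE,
    high_basal_fold: float = 2.0,
    hyper_fold: float = 2.5,
    low_basal_fold: float = 2.0,
    bimodal_minor_weight: float = _BIMODAL_MINOR_WEIGHT,
    background_weight: float = 0.01,
    background_scale: float = 1.0,
) -> GfpModel:
    """Documented default class models.

    HIGH_BASAL sits ``high_basal_fold`` (default two-fold) above the WT
    basal median and induces normally; NON_INDUCER equals WT basal under
    both conditions; GFP_NEG equals the dark control under both; BIMODAL is
    a dark majority plus a ``bimodal_minor_weight`` minority that behaves
    like WT.

    Every class carries a broad ``background_weight`` component spanning
    the axis (autofluorescence outliers / doublets / sorting impurity).
    Without it, narrow gates would capture literally zero cells of
    non-matching classes and sorted pools would consist solely of the
    enriched mutants — unlike real sorts, whose regrown pools are visibly
    impure — which would leave median-of-ratios normalization without a
    stable unenriched baseline.
    """
    bg = (background_weight,
          0.5 * (dark_loc + induced_loc), background_scale)

    def mix(*comps: tuple[float, float, float]):
        main = tuple((w * (1 - background_weight), loc, s) for w, loc, s in comps)
        return main + (bg,) if background_weight > 0 else main

    one = lambda loc: mix((1.0, loc, scale))  # noqa: E731
    w = bimodal_minor_weight
    return GfpModel(components={
        PhenotypeClass.WT: {UNINDUCED: one(basal_loc), INDUCED: one(induced_loc)},
        PhenotypeClass.GFP_NEG: {UNINDUCED: one(dark_loc), INDUCED: one(dark_loc)},
        PhenotypeClass.NON_INDUCER: {UNINDUCED: one(basal_loc), INDUCED: one(basal_loc)},
        PhenotypeClass.HIGH_BASAL: {
            UNINDUCED: one(basal_loc + math.log10(high_basal_fold)),
            INDUCED: one(induced_loc),
        },
        PhenotypeClass.HYPER_INDUCER: {
            UNINDUCED: one(basal_loc),
            INDUCED: one(induced_loc + math.log10(hyper_fold)),
        },
        PhenotypeClass.LOW_BASAL: {
            UNINDUCED: one(basal_loc - math.log10(low_basal_fold)),
            INDUCED: one(induced_loc),
        },
        PhenotypeClass.BIMODAL: {
            UNINDUCED: mix((1 - w, dark_loc, scale), (w, basal_loc, scale)),
            INDUCED: mix((1 - w, dark_loc, scale), (w, induced_loc, scale)),
        },
    })


@dataclass(frozen=True)
class Gate:
    """Half-open fluorescence interval ``[lower, upper)`` on the log10 axis."""

    name: str
    condition: str
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"gate {self.name}: lower must be < upper")
        if self.name in GATE_NAMES:
            expect = UNINDUCED if self.name.startswith("Un_") else INDUCED
            if self.condition != expect:
                raise ValueError(f"gate {self.name}: condition must be {expect!r}")


class GateConfigError(ValueError):
    """Control distributions too entangled for the requested percentiles."""


def derive_gates(
    control_samples: dict[str, np.ndarray],
    percentiles: tuple[float, float] = (1.0, 99.0),
) -> list[Gate]:
    """Set the five screen gates from control-strain fluorescence draws.

    ``control_samples`` must provide log10-GFP draws for ``"gfp_neg"``
    (dark control), ``"basal"`` (uninduced wild type) and ``"induced"``
    (induced wild type).  The dark gate's upper bound is placed between the
    dark control's upper percentile and the basal control's lower
    percentile; the super-induced gate starts at the induced control's
    upper percentile.
    """
    lo_pct, hi_pct = percentiles
    q = {}
    for key in ("gfp_neg", "basal", "induced"):
        sample = np.asarray(control_samples.get(key, ()), dtype=float)
        if sample.size == 0:
            raise ValueError(f"control sample {key!r} missing or empty")
        q[key] = (np.percentile(sample, lo_pct), np.percentile(sample, hi_pct))

    if not q["gfp_neg"][1] < q["basal"][0]:
        raise GateConfigError(
            "dark and basal controls overlap at the requested percentiles "
            f"({q['gfp_neg'][1]:.3f} >= {q['basal'][0]:.3f})"
        )
    if not q["basal"][1] < q["induced"][0]:
        raise GateConfigError(
            "basal and induced controls overlap at the requested percentiles "
            f"({q['basal'][1]:.3f} >= {q['induced'][0]:.3f})"
        )
    neg_upper = 0.5 * (q["gfp_neg"][1] + q["basal"][0])
    basal_lo, basal_hi = q["basal"]
    pp_lower = q["induced"][1]
    return [
        Gate("Un_Gfp_neg", UNINDUCED, -np.inf, neg_upper),
        Gate("Un_Gfp_plus", UNINDUCED, basal_hi, np.inf),
        Gate("In_Gfp_neg", INDUCED, -np.inf, neg_upper),
        Gate("In_Gfp_basal", INDUCED, basal_lo, basal_hi),
        Gate("In_Gfp_plusplus", INDUCED, pp_lower, np.inf),
    ]


def default_gates(model: GfpModel, n_control_cells: int = 100_000,
                  seed: int = 0) -> list[Gate]:
    """Gates derived from simulated control draws under ``model``."""
    rng = np.random.default_rng(seed)
    controls = {
        "gfp_neg": model.sample(PhenotypeClass.GFP_NEG, UNINDUCED, n_control_cells, rng),
        "basal": model.sample(PhenotypeClass.WT, UNINDUCED, n_control_cells, rng),
        "induced": model.sample(PhenotypeClass.WT, INDUCED, n_control_cells, rng),
    }
    return derive_gates(controls)


@dataclass(frozen=True)
class MutantSpec:
    gene: str
    phenotype: PhenotypeClass
    pool_abundance: float
    fitness: float = 1.0

    def __post_init__(self) -> None:
        if self.pool_abundance <= 0:
            raise ValueError(f"{self.gene}: pool_abundance must be > 0")
        if self.fitness <= 0:
            raise ValueError(f"{self.gene}: fitness must be > 0")


def make_mutant_pool(
    genes: list[str],
    classes: dict[str, PhenotypeClass] | None = None,
    abundances: dict[str, float] | None = None,
    fitness: dict[str, float] | None = None,
) -> list[MutantSpec]:
    """Uniform-abundance pool; unlisted genes are WT with fitness 1."""
    classes = classes or {}
    fitness = fitness or {}
    if abundances is None:
        abundances = {g: 1.0 / len(genes) for g in genes}
    total = sum(abundances[g] for g in genes)
    return [
        MutantSpec(
            gene=g,
            phenotype=classes.get(g, PhenotypeClass.WT),
            pool_abundance=abundances[g] / total,
            fitness=fitness.get(g, 1.0),
        )
        for g in genes
    ]


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_cells_sorted: int = 100_000
    regrowth_generations: int = 5
    pcr_noise_sd: float = 0.10
    per_base_error_rate: float = 0.001
    reads_per_sample: int = 50_000
    replicates: int = 3
    read_length: int = 50

    def __post_init__(self) -> None:
        if not 0 <= self.per_base_error_rate <= 1:
            raise ValueError("per_base_error_rate must be in [0,1]")
        for name in ("n_cells_sorted", "regrowth_generations", "reads_per_sample",
                     "replicates", "read_length"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.pcr_noise_sd < 0:
            raise ValueError("pcr_noise_sd must be >= 0")


# ---------------------------------------------------------------------------
# population / sorting / regrowth


def simulate_population(
    mutants: list[MutantSpec],
    model: GfpModel,
    condition: str,
    n_cells: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw a cell table (gene, log10_gfp) from the pool composition.

    Mutant identities are multinomial in pool abundance; fluorescence is
    drawn per cell from the mutant's class/condition mixture.
    """
    abund = np.array([m.pool_abundance for m in mutants])
    if not math.isclose(abund.sum(), 1.0, rel_tol=1e-9):
        raise ValueError("pool abundances must sum to 1")
    if n_cells == 0:
        return pd.DataFrame({"gene": pd.Series([], dtype=str),
                             "log10_gfp": pd.Series([], dtype=float)})
    counts = rng.multinomial(n_cells, abund)
    genes = np.repeat([m.gene for m in mutants], counts)
    gfp = np.empty(n_cells)
    pos = 0
    for m, c in zip(mutants, counts):
        if c:
            gfp[pos : pos + c] = model.sample(m.phenotype, condition, int(c), rng)
            pos += c
    return pd.DataFrame({"gene": genes, "log10_gfp": gfp})


def apply_gate(cells: pd.DataFrame, gate: Gate) -> pd.DataFrame:
    """Cells with ``gate.lower <= log10_gfp < gate.upper``, order preserved."""
    x = cells["log10_gfp"].to_numpy()
    return cells[(x >= gate.lower) & (x < gate.upper)]


def regrow(
    counts: pd.Series,
    fitness: pd.Series | float,
    generations: int,
    rng: np.random.Generator,
) -> pd.Series:
    """Grow a pool: fitness^generations reweighting + multinomial resampling.

    The total cell count is conserved; with all fitness 1 the only change
    is multinomial drift.
    """
    if (counts < 0).any():
        raise ValueError("counts must be >= 0")
    total = int(counts.sum())
    if total == 0:
        return counts.iloc[0:0]
    if np.isscalar(fitness):
        fitness = pd.Series(float(fitness), index=counts.index)
    w = counts.to_numpy(dtype=float) * fitness.reindex(counts.index).to_numpy() ** generations
    p = w / w.sum()
    return pd.Series(rng.multinomial(total, p), index=counts.index)


# ---------------------------------------------------------------------------
# PCR + sequencing


def _encode(seq: str) -> np.ndarray:
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    lut = np.full(256, 255, dtype=np.uint8)
    lut[np.frombuffer(b"ACGT", dtype=np.uint8)] = np.arange(4, dtype=np.uint8)
    enc = lut[codes]
    if (enc == 255).any():
        raise ValueError(f"non-ACGT base in sequence {seq!r}")
    return enc


def amplify_and_sequence(
    composition: pd.Series,
    catalog: BarcodeCatalog,
    layout: AmpliconLayout,
    multiplex_tag: str,
    tag: str,
    config: SimConfig,
    rng: np.random.Generator,
    read_prefix: str = "read",
) -> tuple[list[ReadRecord], pd.Series]:
    """PCR-amplify and sequence one pool's barcodes for one tag.

    Per-gene read share is the composition share distorted by a log-normal
    PCR efficiency factor (sd ``pcr_noise_sd``); each read is multiplex tag
    + upstream primer + barcode + downstream primer, truncated or padded
    (with A) to ``read_length``, with independent per-base substitution
    errors.  Returns ``(reads, assigned_counts)`` where ``assigned_counts``
    is the realized multinomial read draw per gene — the exact target for
    noise-free downstream counting.
    """
    if len(multiplex_tag) != layout.multiplex_tag_length:
        raise ValueError("multiplex tag length does not match layout")
    genes = [g for g in composition.index if composition[g] > 0]
    missing = [g for g in genes if g not in catalog]
    if missing:
        raise KeyError(f"genes absent from catalog: {missing[:5]}")
    empty_counts = pd.Series(0, index=composition.index, dtype=int)
    if config.reads_per_sample == 0 or not genes:
        return [], empty_counts

    share = composition[genes].to_numpy(dtype=float)
    if config.pcr_noise_sd > 0:
        share = share * rng.lognormal(0.0, config.pcr_noise_sd, size=len(genes))
    share = share / share.sum()
    draw = rng.multinomial(config.reads_per_sample, share)
    assigned = empty_counts.copy()
    assigned[genes] = draw

    L = config.read_length
    templates = np.zeros((len(genes), L), dtype=np.uint8)
    for i, g in enumerate(genes):
        bcs = catalog.lookup(g).barcodes("up" if tag == "up" else "dn")
        if not bcs:
            raise KeyError(f"gene {g} has no {tag}tag barcode")
        full = multiplex_tag + layout.upstream_primer + bcs[0] + layout.downstream_primer
        full = (full + "A" * L)[:L]
        templates[i] = _encode(full)

    reads_mat = np.repeat(templates, draw, axis=0)
    order = rng.permutation(len(reads_mat))
    reads_mat = reads_mat[order]
    read_genes = np.repeat(np.array(genes, dtype=object), draw)[order]

    if config.per_base_error_rate > 0:
        mask = rng.random(reads_mat.shape) < config.per_base_error_rate
        n_err = int(mask.sum())
        if n_err:
            shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
            reads_mat[mask] = (reads_mat[mask] + shift) % 4

    ascii_mat = _BASE_CODES[reads_mat]
    qual = "I" * L
    records = [
        ReadRecord(
            id=f"{read_prefix}:{i}:{read_genes[i]}",
            sequence=ascii_mat[i].tobytes().decode("ascii"),
            quality=qual,
        )
        for i in range(len(ascii_mat))
    ]
    return records, assigned


# ---------------------------------------------------------------------------
# whole screen


def random_barcodes(
    n: int, length: int, rng: np.random.Generator, min_distance: int = 5
) -> list[str]:
    """Distinct random barcodes with pairwise Hamming distance >= min_distance.

    Random 20-mers are typically ~15 apart, so rejection is rare; the
    separation guarantees unique minimal-distance matching at the default
    mismatch radius.  Conflicting candidates are dropped and redrawn.
    """
    if min_distance > length:
        raise ValueError("min_distance cannot exceed barcode length")
    for _ in range(50):
        m = n + 8  # small oversample: violations are rare events
        codes = rng.integers(0, 4, size=(m, length)).astype(np.uint8)
        drop: set[int] = set()
        for start in range(0, m, 256):  # chunked pairwise check, memory-bounded
            chunk = codes[start : start + 256]
            dist = (chunk[:, None, :] != codes[None, :, :]).sum(axis=2)
            for i in range(len(chunk)):
                dist[i, start + i] = length
            for a, b in np.argwhere(dist < min_distance):
                drop.add(max(start + int(a), int(b)))
        keep = [i for i in range(m) if i not in drop][:n]
        if len(keep) == n:
            return [_BASE_CODES[codes[i]].tobytes().decode("ascii") for i in keep]
    raise RuntimeError(
        f"cannot place {n} barcodes of length {length} at distance {min_distance}"
    )


def random_catalog(
    n_genes: int,
    rng: np.random.Generator,
    layout: AmpliconLayout | None = None,
    min_distance: int = 5,
    gene_prefix: str = "G",
) -> BarcodeCatalog:
    """Synthetic catalog: n_genes with distinct random up and dn barcodes."""
    layout = layout or AmpliconLayout()
    codes = random_barcodes(2 * n_genes, layout.barcode_length, rng, min_distance)
    width = max(4, len(str(n_genes)))
    entries = [
        CatalogEntry(
            gene=f"{gene_prefix}{i + 1:0{width}d}",
            uptag=codes[2 * i],
            dntag=codes[2 * i + 1],
            source="primary_list",
        )
        for i in range(n_genes)
    ]
    return BarcodeCatalog(entries=entries, layout=layout)


def demo_mutant_pool(
    genes: list[str],
    class_counts: dict[PhenotypeClass, int],
    rng: np.random.Generator,
) -> list[MutantSpec]:
    """Uniform pool in which randomly chosen genes carry non-WT classes."""
    total = sum(class_counts.values())
    if total > len(genes):
        raise ValueError("more class assignments than genes")
    chosen = rng.choice(len(genes), size=total, replace=False)
    classes: dict[str, PhenotypeClass] = {}
    pos = 0
    for cls, count in class_counts.items():
        for idx in chosen[pos : pos + count]:
            classes[genes[int(idx)]] = cls
        pos += count
    return make_mutant_pool(genes, classes=classes)


def generate_multiplex_tags(
    n: int, length: int, rng: np.random.Generator, min_distance: int = 3
) -> list[str]:
    """Greedy random tag set with pairwise Hamming distance >= min_distance."""
    tags: list[np.ndarray] = []
    attempts = 0
    while len(tags) < n:
        cand = rng.integers(0, 4, size=length).astype(np.uint8)
        if all(int((cand != t).sum()) >= min_distance for t in tags):
            tags.append(cand)
        attempts += 1
        if attempts > 100_000:
            raise RuntimeError(
                f"cannot place {n} tags of length {length} at distance {min_distance}"
            )
    return [_BASE_CODES[t].tobytes().decode("ascii") for t in tags]


def truth_table(
    mutants: list[MutantSpec], model: GfpModel, gates: list[Gate]
) -> pd.DataFrame:
    """Analytic per-mutant gate-capture probabilities and enrichment signs.

    ``p_<gate>`` is the probability a cell of that mutant falls in the gate;
    ``sign_<gate>`` compares the mutant's capture probability with the
    abundance-weighted pool average (+1 above 2x, -1 below 0.5x, else 0).
    """
    rows = []
    cap = {
        g.name: np.array([
            model.gate_probability(m.phenotype, g.condition, g.lower, g.upper)
            for m in mutants
        ])
        for g in gates
    }
    abund = np.array([m.pool_abundance for m in mutants])
    for i, m in enumerate(mutants):
        row: dict[str, object] = {"gene": m.gene, "phenotype": m.phenotype.value,
                                  "abundance": m.pool_abundance, "fitness": m.fitness}
        for g in gates:
            p = cap[g.name][i]
            pool_mean = float(abund @ cap[g.name])
            ratio = p / pool_mean if pool_mean > 0 else np.inf
            row[f"p_{g.name}"] = p
            row[f"sign_{g.name}"] = 1 if ratio > 2 else (-1 if ratio < 0.5 else 0)
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene")


@dataclass
class ScreenOutput:
    """Everything a simulated screen run emits."""

    sample_sheet: pd.DataFrame  # sample, pool, replicate, bar_tag, multiplex_tag, fastq
    truth: pd.DataFrame
    assigned_counts: pd.DataFrame  # genes x samples: realized read draws
    gates: list[Gate]

    def fastq_paths(self) -> dict[str, Path]:
        return {r.sample: Path(r.fastq) for r in self.sample_sheet.itertuples()}


def simulate_screen(
    mutants: list[MutantSpec],
    model: GfpModel,
    gates: list[Gate],
    catalog: BarcodeCatalog,
    config: SimConfig,
    outdir: str | Path,
) -> ScreenOutput:
    """Run the full simulated screen and write FASTQ + truth to ``outdir``.

    Per replicate: a presorted-library sample plus one sample per gate,
    each sequenced as UPTAG and DNTAG streams under distinct multiplex
    tags.  Sorted pools are regrown before sequencing; the presorted
    library is sequenced directly from a sampled composition.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    layout = catalog.layout
    pools = ["presorted"] + [g.name for g in gates]
    n_streams = config.replicates * len(pools) * 2
    tags = generate_multiplex_tags(n_streams, layout.multiplex_tag_length, rng)

    gene_index = pd.Index([m.gene for m in mutants], name="gene")
    abund = pd.Series([m.pool_abundance for m in mutants], index=gene_index)
    fitness = pd.Series([m.fitness for m in mutants], index=gene_index)

    sheet_rows = []
    count_cols: dict[str, pd.Series] = {}
    tag_iter = iter(tags)
    for rep in range(1, config.replicates + 1):
        compositions: dict[str, pd.Series] = {}
        presort = pd.Series(
            rng.multinomial(config.n_cells_sorted, abund.to_numpy()), index=gene_index
        )
        compositions["presorted"] = presort
        for condition in (UNINDUCED, INDUCED):
            cells = simulate_population(mutants, model, condition, config.n_cells_sorted, rng)
            for gate in gates:
                if gate.condition != condition:
                    continue
                pool_cells = apply_gate(cells, gate)
                counts = pool_cells["gene"].value_counts().reindex(gene_index, fill_value=0)
                compositions[gate.name] = regrow(
                    counts, fitness, config.regrowth_generations, rng
                )
        for pool in pools:
            comp = compositions[pool]
            for bar_tag in ("up", "dn"):
                mtag = next(tag_iter)
                sample = f"{pool}_rep{rep}_{bar_tag}"
                reads, assigned = amplify_and_sequence(
                    comp, catalog, layout, mtag, bar_tag, config, rng,
                    read_prefix=sample,
                )
                fastq = outdir / f"{sample}.fastq"
                write_fastq(reads, fastq)
                count_cols[sample] = assigned.reindex(gene_index, fill_value=0)
                sheet_rows.append({
                    "sample": sample, "pool": pool, "replicate": rep,
                    "bar_tag": bar_tag, "multiplex_tag": mtag, "fastq": str(fastq),
                })

    sheet = pd.DataFrame(sheet_rows)
    truth = truth_table(mutants, model, gates)
    assigned_counts = pd.DataFrame(count_cols).reindex(gene_index).astype(int)
    sheet.to_csv(outdir / "sample_sheet.tsv", sep="\t", index=False)
    truth.to_csv(outdir / "truth_table.tsv", sep="\t")
    assigned_counts.to_csv(outdir / "assigned_read_counts.tsv", sep="\t")
    pd.DataFrame(
        [{"name": g.name, "condition": g.condition, "lower": g.lower, "upper": g.upper}
         for g in gates]
    ).to_csv(outdir / "gates.tsv", sep="\t", index=False)
    return ScreenOutput(sample_sheet=sheet, truth=truth,
                        assigned_counts=assigned_counts, gates=gates)
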