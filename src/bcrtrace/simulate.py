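"""Synthetic longitudinal single-cell BCR repertoires with ground truth.

The generator emulates the data shape of a single-donor vaccination time
course profiled by single-cell V(D)J sequencing: clones with power-law
sizes, paired heavy/light chains, per-visit sampling, per-visit isotype
composition with switches only moving forward along the IGH constant-gene
order, Poisson somatic hypermutation over a germline V region (optionally
coupled between a cell's heavy and light chain through a shared gamma
factor), and optional planted near-copies of query junctions. Every chain
is emitted in the canonical AIRR-named schema together with ground-truth
tables (true clone labels, true per-region mutation maps, planted-hit
lists), so downstream modules can be validated without any external data.

All randomness flows through one seeded NumPy generator; a fixed seed
yields byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from bcrtrace.clonotype import junction_identity
from bcrtrace.csr import ISOTYPE_ORDER
from bcrtrace.errors import BcrtraceError, ParameterError
from bcrtrace.io import ChainTable, translate_nt

# IMGT-style V-region layout used for every simulated germline (0-based,
# half-open, codon-aligned; 300 nt total)
V_LENGTH = 300
REGION_BOUNDS = {
    "fwr1": (0, 75),
    "cdr1": (75, 99),
    "fwr2": (99, 150),
    "cdr2": (150, 174),
    "fwr3": (174, 300),
}

_AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

# one representative codon per amino acid (standard code)
_CODON_OF = {
    "A": "GCT", "C": "TGC", "D": "GAT", "E": "GAA", "F": "TTC", "G": "GGT",
    "H": "CAC", "I": "ATC", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAC",
    "P": "CCT", "Q": "CAG", "R": "CGT", "S": "TCT", "T": "ACC", "V": "GTG",
    "W": "TGG", "Y": "TAC",
}

DEFAULT_V_POOL = {
    "IGHV1-2": 0.05, "IGHV1-18": 0.05, "IGHV1-69": 0.05, "IGHV2-5": 0.04,
    "IGHV3-7": 0.06, "IGHV3-23": 0.12, "IGHV3-30": 0.06, "IGHV3-33": 0.07,
    "IGHV4-31": 0.05, "IGHV4-34": 0.07, "IGHV4-39": 0.06, "IGHV4-59": 0.06,
    "IGHV5-51": 0.08, "IGHV6-1": 0.04, "IGHV1-46": 0.05, "IGHV3-48": 0.09,
}
DEFAULT_J_POOL = {
    "IGHJ1": 0.03, "IGHJ2": 0.05, "IGHJ3": 0.08,
    "IGHJ4": 0.40, "IGHJ5": 0.14, "IGHJ6": 0.30,
}
DEFAULT_KAPPA_V_POOL = {"IGKV1-39": 0.3, "IGKV3-20": 0.3, "IGKV1-5": 0.2, "IGKV4-1": 0.2}
DEFAULT_LAMBDA_V_POOL = {"IGLV1-44": 0.35, "IGLV2-14": 0.35, "IGLV3-21": 0.3}
DEFAULT_KAPPA_J_POOL = {"IGKJ1": 0.4, "IGKJ2": 0.3, "IGKJ4": 0.3}
DEFAULT_LAMBDA_J_POOL = {"IGLJ2": 0.5, "IGLJ3": 0.5}

DEFAULT_VISITS = {
    "d0_B": 0.15, "d0_PC": 0.10, "d5": 0.30, "d7": 0.20, "d10": 0.15, "d14": 0.10,
}

# per-visit constant-gene composition: naive IgM/IgD at baseline B cells,
# switched IgG1/IgA1-dominated antibody-secreting cells after the boost
DEFAULT_ISOTYPES = {
    "d0_B": {"IGHM": 0.55, "IGHD": 0.20, "IGHG3": 0.05, "IGHG1": 0.10, "IGHA1": 0.10},
    "d0_PC": {"IGHM": 0.20, "IGHG3": 0.08, "IGHG1": 0.40, "IGHA1": 0.22, "IGHG2": 0.05, "IGHA2": 0.05},
    "d5": {"IGHM": 0.10, "IGHG3": 0.06, "IGHG1": 0.50, "IGHA1": 0.24, "IGHG2": 0.06, "IGHA2": 0.04},
    "d7": {"IGHM": 0.08, "IGHG3": 0.06, "IGHG1": 0.52, "IGHA1": 0.24, "IGHG2": 0.06, "IGHA2": 0.04},
    "d10": {"IGHM": 0.10, "IGHG3": 0.05, "IGHG1": 0.48, "IGHA1": 0.25, "IGHG2": 0.07, "IGHA2": 0.05},
    "d14": {"IGHM": 0.12, "IGHG3": 0.05, "IGHG1": 0.45, "IGHA1": 0.26, "IGHG2": 0.07, "IGHA2": 0.05},
}


@dataclass
class SimConfig:
    """Study conditions for a synthetic repertoire.

    Defaults follow the longitudinal single-donor vaccination setting the
    toolkit targets: CDR3 amino-acid lengths ~ Normal(15.8, 3.8), power-law
    clone sizes (exponent 2.5, capped at 129 members), a 3:2 kappa:lambda
    ratio, and visit-dependent isotype composition.
    """

    n_clones: int = 300
    clone_size_exponent: float = 2.5
    clone_size_max: int = 129
    v_gene_pool: dict = field(default_factory=lambda: dict(DEFAULT_V_POOL))
    j_gene_pool: dict = field(default_factory=lambda: dict(DEFAULT_J_POOL))
    cdr3_length_mean: float = 15.8
    cdr3_length_sd: float = 3.8
    shm_rate: float = 0.02  # per-base substitution probability over the V region
    shared_cell_rate_shape: float | None = 2.0  # gamma shape coupling heavy/light loads
    kappa_fraction: float = 0.6  # the normal human 3:2 kappa:lambda ratio
    isotype_transition: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_ISOTYPES.items()})
    visits: dict = field(default_factory=lambda: dict(DEFAULT_VISITS))
    unproductive_fraction: float = 0.05
    secondary_chain_fraction: float = 0.05
    planted_queries: list = field(default_factory=list)  # (junction_aa, n_copies, (lo, hi))
    seed: int = 0

    def validate(self) -> None:
        if self.n_clones < 1:
            raise ParameterError("n_clones must be >= 1")
        if self.clone_size_max < 1:
            raise ParameterError("clone_size_max must be >= 1")
        if not (0 <= self.shm_rate < 1):
            raise ParameterError("shm_rate must be in [0, 1)")
        if not (0 <= self.kappa_fraction <= 1):
            raise ParameterError("kappa_fraction must be in [0, 1]")
        for name, pool in (
            ("v_gene_pool", self.v_gene_pool),
            ("j_gene_pool", self.j_gene_pool),
            ("visits", self.visits),
        ):
            if not pool or any(w < 0 for w in pool.values()) or sum(pool.values()) <= 0:
                raise ParameterError(f"{name} must have non-negative weights with positive sum")
        for visit, vec in self.isotype_transition.items():
            if abs(sum(vec.values()) - 1.0) > 1e-9:
                raise ParameterError(f"isotype probabilities for {visit} must sum to 1")
            unknown = set(vec) - set(ISOTYPE_ORDER)
            if unknown:
                raise ParameterError(f"unknown constant genes for {visit}: {sorted(unknown)}")
        missing = set(self.visits) - set(self.isotype_transition)
        if missing:
            raise ParameterError(f"visits without isotype vectors: {sorted(missing)}")


def _weighted_choice(rng, pool: dict) -> str:
    keys = list(pool)
    weights = np.array([pool[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=weights / weights.sum())]


def _random_dna(rng, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def _aa_to_nt(aa: str) -> str:
    return "".join(_CODON_OF[r] for r in aa)


def _mutate(rng, sequence: str, n_mut: int) -> tuple[str, list[int]]:
    """Apply n distinct random substitutions; returns (mutated, positions)."""
    n_mut = min(n_mut, len(sequence))
    positions = sorted(rng.choice(len(sequence), size=n_mut, replace=False).tolist())
    seq = list(sequence)
    for pos in positions:
        alternatives = [b for b in "ACGT" if b != seq[pos]]
        seq[pos] = alternatives[rng.integers(0, 3)]
    return "".join(seq), positions


def _region_of(pos: int) -> str:
    for region, (start, end) in REGION_BOUNDS.items():
        if start <= pos < end:
            return region
    return "outside"


def simulate_repertoire(config: SimConfig | None = None) -> tuple[ChainTable, dict]:
    """Generate a repertoire and its ground truth.

    Returns the chain table (heavy + paired light chains, plus planted
    unproductive and low-read decoy contigs exercising the filters) and a
    dict of ground-truth tables: ``clones`` (true heavy-chain clone
    labels), ``mutations`` (true per-region substitution counts per
    chain), ``planted_hits`` (inserted query variants), ``germlines``
    (gene -> V sequence), ``decoys`` and ``unproductive`` (sequence ids
    the read filters should remove).
    """
    config = config or SimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    germlines = {
        gene: _random_dna(rng, V_LENGTH)
        for gene in (
            list(config.v_gene_pool)
            + list(DEFAULT_KAPPA_V_POOL)
            + list(DEFAULT_LAMBDA_V_POOL)
        )
    }

    sizes = np.arange(1, config.clone_size_max + 1)
    size_p = sizes.astype(float) ** -config.clone_size_exponent
    size_p /= size_p.sum()

    visit_labels = list(config.visits)
    visit_p = np.array([config.visits[v] for v in visit_labels], dtype=float)
    visit_p /= visit_p.sum()

    rows: list[dict] = []
    truth_clones: list[dict] = []
    truth_mut: list[dict] = []
    decoys: list[str] = []
    unproductive: list[str] = []
    cell_serial = 0

    for clone_idx in range(config.n_clones):
        v_gene = _weighted_choice(rng, config.v_gene_pool)
        j_gene = _weighted_choice(rng, config.j_gene_pool)
        is_kappa = rng.random() < config.kappa_fraction
        lv_pool = DEFAULT_KAPPA_V_POOL if is_kappa else DEFAULT_LAMBDA_V_POOL
        lj_pool = DEFAULT_KAPPA_J_POOL if is_kappa else DEFAULT_LAMBDA_J_POOL
        lv_gene = _weighted_choice(rng, lv_pool)
        lj_gene = _weighted_choice(rng, lj_pool)
        light_locus = "IGK" if is_kappa else "IGL"

        cdr3_len = int(np.clip(round(rng.normal(config.cdr3_length_mean, config.cdr3_length_sd)), 5, 32))
        cdr3_aa = "".join(_AA_ALPHABET[i] for i in rng.integers(0, 20, size=cdr3_len))
        junction_aa = "C" + cdr3_aa + "W"
        junction_nt = _aa_to_nt(junction_aa)
        light_len = int(np.clip(round(rng.normal(9.5, 1.5)), 5, 14))
        light_cdr3_aa = "".join(_AA_ALPHABET[i] for i in rng.integers(0, 20, size=light_len))
        light_junction_aa = "C" + light_cdr3_aa + "F"
        light_junction_nt = _aa_to_nt(light_junction_aa)

        size = int(rng.choice(sizes, p=size_p))
        # sample member visits/isotypes i.i.d. from the per-visit vectors,
        # then order members by switch rank so the clone's generative
        # lineage (each member descends from an earlier one) only ever
        # switches forward
        members = []
        for _ in range(size):
            visit = visit_labels[rng.choice(len(visit_labels), p=visit_p)]
            members.append((visit, _weighted_choice(rng, config.isotype_transition[visit])))
        members.sort(key=lambda m: ISOTYPE_ORDER.index(m[1]))

        for visit, isotype in members:
            cell_serial += 1
            cell_id = f"cell{cell_serial:05d}"
            gamma = (
                float(rng.gamma(config.shared_cell_rate_shape, 1.0 / config.shared_cell_rate_shape))
                if config.shared_cell_rate_shape
                else 1.0
            )
            reads = int(rng.integers(100, 500))
            for locus, vg, jg, junc_nt, junc_aa, cg in (
                ("IGH", v_gene, j_gene, junction_nt, junction_aa, isotype),
                (light_locus, lv_gene, lj_gene, light_junction_nt, light_junction_aa, None),
            ):
                germ = germlines[vg]
                n_mut = int(rng.poisson(config.shm_rate * V_LENGTH * gamma))
                observed, positions = _mutate(rng, germ, n_mut)
                seq_id = f"{cell_id}_{locus}"
                rows.append(
                    {
                        "sequence_id": seq_id,
                        "cell_id": cell_id,
                        "locus": locus,
                        "v_call": f"{vg}*01",
                        "d_call": "IGHD3-10*01" if locus == "IGH" else pd.NA,
                        "j_call": f"{jg}*01",
                        "c_call": cg if locus == "IGH" else ("IGKC" if locus == "IGK" else "IGLC2"),
                        "productive": True,
                        "junction": junc_nt,
                        "junction_aa": junc_aa,
                        "cdr3": junc_nt[3:-3],
                        "cdr3_aa": junc_aa[1:-1],
                        "read_count": reads,
                        "umi_count": int(rng.integers(1, 20)),
                        "visit": visit,
                        "sequence_alignment": observed,
                        "germline_alignment": germ,
                        **{
                            f"{r}_{endpoint}": REGION_BOUNDS[r][i]
                            for r in REGION_BOUNDS
                            for i, endpoint in enumerate(("start", "end"))
                        },
                    }
                )
                region_counts = dict.fromkeys(list(REGION_BOUNDS) + ["outside"], 0)
                for pos in positions:
                    region_counts[_region_of(pos)] += 1
                truth_mut.append(
                    {"sequence_id": seq_id, "cell_id": cell_id, "locus": locus,
                     "total_v": len(positions), **region_counts}
                )
                if locus == "IGH":
                    truth_clones.append(
                        {"sequence_id": seq_id, "true_clone": clone_idx + 1,
                         "v_gene": vg, "j_gene": jg, "visit": visit}
                    )
            # planted filter fodder: an unproductive contig or a low-read
            # secondary heavy chain on a subset of cells
            roll = rng.random()
            if roll < config.unproductive_fraction:
                seq_id = f"{cell_id}_IGH_unprod"
                rows.append(_decoy_row(rows[-2], seq_id, productive=False, reads=int(rng.integers(10, 50))))
                unproductive.append(seq_id)
            elif roll < config.unproductive_fraction + config.secondary_chain_fraction:
                seq_id = f"{cell_id}_IGH_low"
                rows.append(_decoy_row(rows[-2], seq_id, productive=True, reads=int(rng.integers(1, max(2, reads // 20)))))
                decoys.append(seq_id)

    table = ChainTable(pd.DataFrame(rows), dialect="airr")
    planted = []
    for query_aa, n_copies, band in config.planted_queries:
        table, ids = plant_query_variants(
            table, query_aa, n_copies, band, seed=int(rng.integers(0, 2**31 - 1))
        )
        planted.extend(
            {"query": query_aa, "sequence_id": sid, "identity": junction_identity(query_aa, j)}
            for sid, j in ids
        )

    truth = {
        "clones": pd.DataFrame(truth_clones),
        "mutations": pd.DataFrame(truth_mut),
        "planted_hits": pd.DataFrame(planted, columns=["query", "sequence_id", "identity"]),
        "germlines": germlines,
        "decoys": decoys,
        "unproductive": unproductive,
        "config": config,
    }
    return table, truth


def _decoy_row(template: dict, seq_id: str, productive: bool, reads: int) -> dict:
    row = dict(template)
    row.update(sequence_id=seq_id, productive=productive, read_count=reads)
    return row


def plant_query_variants(
    table: ChainTable,
    query: str,
    n: int,
    identity_band: tuple[float, float],
    seed: int = 0,
) -> tuple[ChainTable, list[tuple[str, str]]]:
    """Insert ``n`` chains whose junction is the query mutated into a band.

    The planted junction's Levenshtein identity to ``query`` lies within
    ``identity_band`` (substitution-only mutation keeps lengths equal, so
    identity = 1 - k/len for k substitutions). Returns the augmented table
    and the planted (sequence_id, junction_aa) pairs as ground truth.
    """
    lo, hi = identity_band
    if not (0 < lo <= hi <= 1):
        raise ParameterError(f"identity band must satisfy 0 < lo <= hi <= 1, got {identity_band}")
    length = len(query)
    d_min = math.ceil((1 - hi) * length - 1e-9)
    d_max = math.floor((1 - lo) * length + 1e-9)
    if d_min > d_max:
        raise BcrtraceError(
            f"identity band {identity_band} infeasible for a length-{length} query"
        )
    rng = np.random.default_rng(seed)
    new_rows = []
    planted = []
    for i in range(n):
        for _ in range(100):
            k = int(rng.integers(d_min, d_max + 1))
            positions = rng.choice(length, size=k, replace=False)
            seq = list(query)
            for pos in positions:
                seq[pos] = _other_residue(rng, seq[pos])
            candidate = "".join(seq)
            if lo <= junction_identity(query, candidate) <= hi:
                break
        else:  # pragma: no cover - bands are feasible by construction
            raise BcrtraceError(f"could not realize identity band {identity_band}")
        seq_id = f"planted{len(planted) + 1 + len(table.df):05d}_IGH"
        junction_nt = _aa_to_nt(candidate)
        new_rows.append(
            {
                "sequence_id": seq_id,
                "cell_id": f"plantedcell{i + 1:05d}",
                "locus": "IGH",
                "v_call": "IGHV3-23*01",
                "d_call": pd.NA,
                "j_call": "IGHJ4*01",
                "c_call": "IGHG1",
                "productive": True,
                "junction": junction_nt,
                "junction_aa": candidate,
                "cdr3": junction_nt[3:-3],
                "cdr3_aa": candidate[1:-1],
                "read_count": 200,
                "umi_count": 5,
                "visit": "d7",
            }
        )
        planted.append((seq_id, candidate))
    if not new_rows:
        return table, []
    df = pd.concat([table.df, pd.DataFrame(new_rows)], ignore_index=True)
    return ChainTable(df, table.dialect), planted


def _other_residue(rng, residue: str) -> str:
    alternatives = [a for a in _AA_ALPHABET if a != residue]
    return alternatives[rng.integers(0, len(alternatives))]
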