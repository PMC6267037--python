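"""Synthetic bHLH family generator with known ground truth.

Every downstream stage (domain scan, binding classification, intron-pattern
taxonomy, expression filters) is exercised against families produced here:
proteins carrying exactly one planted ~60-aa domain, multi-exon gene models
whose introns sit at chosen domain-relative codons and phases, and
expression/differential-expression tables with planted classes and effects.

Planting is rule-forced: the basic-region residues are constructed so the
binding category of each gene is a deterministic consequence of the residue
rules, and the emitted GTF back-translates the protein exactly (one fixed
codon per amino acid), so a noise-free family is recoverable in full.
Substitution noise, when requested, is applied per position outside the four
rule-bearing positions; the noise draws are coupled across rates (the same
uniform draw decides each position), so corruption sets at a lower rate nest
inside those at a higher rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import AMINO_ACIDS
from .io import GeneModel, ProteinRecord, write_fasta, write_gtf, write_nucleotide_fasta
from .scan import ConsensusDomainScanner, DomainHit, RegionTemplate
from .binding import classify_binding
from .introns import map_introns_to_domain
from .io import AlignmentBlock

# --------------------------------------------------------------------------
# Canonical domain (the consensus the toy seed alignment collapses to)

CANONICAL_BASIC = "ADRERRRSKINEEFARR"  # rules: K9, E13, R16, R17
CANONICAL_HELIX1 = "HNMLERERRRMKLNE"
CANONICAL_LOOP = "LVPGGA"
CANONICAL_HELIX2 = "LSKASVLAETIRYIKELQNQVE"
CANONICAL_DOMAIN = CANONICAL_BASIC + CANONICAL_HELIX1 + CANONICAL_LOOP + CANONICAL_HELIX2

RULE_POSITIONS = (9, 13, 16, 17)
_BASIC_SET = "RKH"
_NONBASIC_FILLER = "ASNQGTVLIE"
# basic-region positions free for composition control (non-rule)
_FREE_BASIC_POSITIONS = tuple(p for p in range(1, 18) if p not in RULE_POSITIONS)

# residues planted at the rule positions, per category; chosen so the
# classification rules force exactly the requested category
_RULE_PLAN = {
    "G_binder": {9: "K", 13: "E", 16: "R", 17: "R"},
    "E_non_G": {9: "A", 13: "E", 16: "R", 17: "A"},
    "non_E_binder": {9: "K", 13: "A", 16: "R", 17: "R"},
    "potential_G_box": {9: "K", 13: "E", 16: "R", 17: "R"},
    "potential_E_box": {9: "A", 13: "E", 16: "R", 17: "A"},
    "non_binder": {9: "K", 13: "A", 16: "A", 17: "R"},
}
_BINDER_CATEGORIES = ("G_binder", "E_non_G", "non_E_binder")


def toy_seed_alignment(n_rows: int = 8) -> AlignmentBlock:
    """Deterministic 8-row, 60-column seed alignment collapsing to the
    canonical domain. The 13 non-rule basic-region columns are made diverse
    (below 50% conservation) so family members may vary their basic-region
    composition without mismatch cost; rule positions and the HLH columns
    are conserved with varied fractions."""
    rng = np.random.default_rng(20181129)
    columns = []
    for pos in range(1, len(CANONICAL_DOMAIN) + 1):
        canonical = CANONICAL_DOMAIN[pos - 1]
        if pos in _FREE_BASIC_POSITIONS:
            # four residues cycling over the rows: modal count 2/8 < 50%
            pool = list(rng.choice(list(AMINO_ACIDS), size=4, replace=False))
            col = [pool[r % 4] for r in range(n_rows)]
        else:
            col = [canonical] * n_rows
            n_subs = int(rng.integers(0, 4))  # keeps majority >= 5/8
            subs = rng.choice(n_rows, size=n_subs, replace=False)
            for r in subs:
                alt = str(rng.choice([a for a in AMINO_ACIDS if a != canonical]))
                col[r] = alt
        columns.append(col)
    rows = [
        (f"seed{r + 1:02d}", "".join(columns[c][r] for c in range(len(columns))))
        for r in range(n_rows)
    ]
    return AlignmentBlock(rows=rows)


# --------------------------------------------------------------------------
# Family specification

#: Table-1-style wheat category proportions used as the default mix
DEFAULT_CATEGORY_MIX = {
    "G_binder": 291 / 571,
    "E_non_G": 85 / 571,
    "non_E_binder": 84 / 571,
    "potential_E_box": 8 / 571,
    "potential_G_box": 3 / 571,
    "non_binder": 100 / 571,
}

#: common intron patterns: intronless, one phase-0 loop intron (the most
#: common pattern), three phase-0 introns at conserved positions, and a
#: two-intron non-zero-phase pattern
DEFAULT_INTRON_BLUEPRINTS = (
    ((), 0.20),
    (((35, 0),), 0.40),
    (((10, 0), (35, 0), (50, 0)), 0.25),
    (((24, 1), (48, 2)), 0.15),
)

DEFAULT_LOOP_DISTRIBUTION = {5: 0.08, 6: 0.64, 7: 0.12, 8: 0.08, 9: 0.05, 10: 0.03}


@dataclass
class FamilySpec:
    """Study conditions for one synthetic family."""

    n_genes: int = 200
    species_labels: tuple[str, ...] = ("wheat",)
    subgenome_fractions: dict[str, float] = field(
        default_factory=lambda: {"A": 0.32, "B": 0.35, "D": 0.33}
    )
    scaffold_fraction: float = 0.03
    binding_category_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_MIX)
    )
    intron_blueprints: tuple = DEFAULT_INTRON_BLUEPRINTS
    loop_length_distribution: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LOOP_DISTRIBUTION)
    )
    domain_length_mode: int = 60
    binder_basic_range: tuple[int, int] = (5, 11)
    expression_class_mix: dict[str, float] = field(
        default_factory=lambda: {"broad": 0.5, "tissue_specific": 0.3, "silent": 0.2}
    )
    tissues: tuple[str, ...] = ("root", "leaf", "spike")
    noise_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for name, simplex in (
            ("subgenome_fractions", self.subgenome_fractions),
            ("binding_category_mix", self.binding_category_mix),
            ("loop_length_distribution", self.loop_length_distribution),
            ("expression_class_mix", self.expression_class_mix),
        ):
            if abs(sum(simplex.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} does not sum to 1")
        blueprint_total = sum(w for _, w in self.intron_blueprints)
        if abs(blueprint_total - 1.0) > 1e-9:
            raise ValueError("intron blueprint weights do not sum to 1")
        min_len = 54 + min(self.loop_length_distribution)
        for signature, _ in self.intron_blueprints:
            for codon, phase in signature:
                if not 1 <= codon <= min_len:
                    raise ValueError(f"blueprint intron codon {codon} outside 1..{min_len}")
                if phase not in {0, 1, 2}:
                    raise ValueError(f"blueprint intron phase {phase} not in {{0,1,2}}")
        mode_loop = max(self.loop_length_distribution, key=self.loop_length_distribution.get)
        if self.domain_length_mode != 54 + mode_loop:
            raise ValueError(
                f"domain_length_mode {self.domain_length_mode} inconsistent with "
                f"modal loop length {mode_loop} (expected {54 + mode_loop})"
            )
        lo, hi = self.binder_basic_range
        binder_weight = sum(self.binding_category_mix.get(c, 0.0) for c in _BINDER_CATEGORIES)
        if binder_weight > 0 and (hi < 5 or lo > 16):
            raise ValueError(
                "spec requests DNA-binder categories but binder_basic_range "
                f"{self.binder_basic_range} cannot reach five basic residues"
            )
        if not 0.0 <= self.noise_rate <= 1.0:
            raise ValueError("noise_rate must be in [0, 1]")
        if not self.tissues and self.expression_class_mix.get("tissue_specific", 0) > 0:
            raise ValueError("tissue_specific class requested but no tissues declared")


@dataclass
class FamilyData:
    """Generated family: sequences, gene models, spliced CDS and truth."""

    proteins: list[ProteinRecord]
    genes: list[GeneModel]
    cds: dict[str, str]
    truth: pd.DataFrame
    spec: FamilySpec


# deterministic back-translation: first codon per amino acid in
# lexicographic codon order (reproducible CDS without a genome)
_CODON_ORDER = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
_STANDARD = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "CAT": "H", "CAC": "H",
    "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E", "TGT": "C", "TGC": "C",
    "TGG": "W", "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R", "AGT": "S",
    "AGC": "S", "AGA": "R", "AGG": "R", "GGT": "G", "GGC": "G", "GGA": "G",
    "GGG": "G",
}
CODON_TABLE = {}
for codon in _CODON_ORDER:
    aa = _STANDARD.get(codon)
    if aa is not None and aa not in CODON_TABLE:
        CODON_TABLE[aa] = codon


def back_translate(protein: str) -> str:
    return "".join(CODON_TABLE[aa] for aa in protein)


def _map_canonical_codon(q: int, loop: int) -> int:
    """Map a codon position on the canonical 60-residue layout (loop 6) onto
    a domain with the given loop length."""
    if q <= 32:
        return q
    if q <= 38:
        return 32 + min(q - 32, loop)
    return q - 38 + 32 + loop


def _build_basic_region(category: str, spec: FamilySpec, rng) -> tuple[str, int]:
    plan = _RULE_PLAN[category]
    fixed_basic = sum(1 for res in plan.values() if res in _BASIC_SET)
    if category in _BINDER_CATEGORIES:
        lo, hi = spec.binder_basic_range
        lo = max(lo, 5, fixed_basic)
        hi = min(hi, fixed_basic + len(_FREE_BASIC_POSITIONS))
        target = int(rng.integers(lo, hi + 1))
    else:
        target = int(rng.integers(fixed_basic, 5))  # stays below five
    extra = target - fixed_basic
    chosen = rng.choice(len(_FREE_BASIC_POSITIONS), size=extra, replace=False)
    chosen_positions = {_FREE_BASIC_POSITIONS[int(i)] for i in chosen}
    region = []
    for pos in range(1, 18):
        if pos in plan:
            region.append(plan[pos])
        elif pos in chosen_positions:
            region.append(str(rng.choice(list(_BASIC_SET))))
        else:
            region.append(str(rng.choice(list(_NONBASIC_FILLER))))
    return "".join(region), target


def _weighted_choice(rng, options: list, weights: list[float]):
    return options[int(rng.choice(len(options), p=np.asarray(weights) / sum(weights)))]


def generate_family(spec: FamilySpec) -> FamilyData:
    """Generate proteins, gene models, spliced CDS and the truth table.

    Identical spec (including seed) gives byte-identical outputs; per-gene
    random streams are keyed by (seed, gene index) so noise rates can be
    varied without perturbing any other draw.
    """
    spec.validate()
    proteins: list[ProteinRecord] = []
    genes: list[GeneModel] = []
    cds_seqs: dict[str, str] = {}
    truth_rows = []
    chrom_cursor: dict[str, int] = {}

    categories = list(spec.binding_category_mix)
    cat_weights = [spec.binding_category_mix[c] for c in categories]
    loops = sorted(spec.loop_length_distribution)
    loop_weights = [spec.loop_length_distribution[l] for l in loops]
    blueprints = [sig for sig, _ in spec.intron_blueprints]
    bp_weights = [w for _, w in spec.intron_blueprints]
    subs = sorted(spec.subgenome_fractions)
    sub_weights = [spec.subgenome_fractions[s] for s in subs]
    classes = list(spec.expression_class_mix)
    class_weights = [spec.expression_class_mix[c] for c in classes]

    for i in range(spec.n_genes):
        rng = np.random.default_rng([spec.seed, i])
        species = spec.species_labels[i % len(spec.species_labels)]
        gene_id = f"{species}_bhlh_{i:04d}"
        transcript_id = f"{gene_id}.1"

        category = _weighted_choice(rng, categories, cat_weights)
        basic_region, basic_count = _build_basic_region(category, spec, rng)
        loop_len = _weighted_choice(rng, loops, loop_weights)
        loop_seq = CANONICAL_LOOP[:loop_len]
        if loop_len > len(CANONICAL_LOOP):
            loop_seq += "".join(
                str(rng.choice(list(_NONBASIC_FILLER)))
                for _ in range(loop_len - len(CANONICAL_LOOP))
            )
        domain = basic_region + CANONICAL_HELIX1 + loop_seq + CANONICAL_HELIX2

        blueprint = _weighted_choice(rng, blueprints, bp_weights)
        expr_class = _weighted_choice(rng, classes, class_weights)
        if expr_class == "tissue_specific":
            expr_class = f"tissue-specific:{_weighted_choice(rng, list(spec.tissues), [1.0] * len(spec.tissues))}"

        # coupled substitution noise outside the rule-bearing positions
        noisy = list(domain)
        for pos in range(1, len(domain) + 1):
            u = rng.random()
            repl = str(rng.choice(list(AMINO_ACIDS)))
            if pos in RULE_POSITIONS:
                continue
            if u < spec.noise_rate:
                noisy[pos - 1] = repl
        domain = "".join(noisy)

        flank_n = "".join(
            str(rng.choice(list(AMINO_ACIDS))) for _ in range(int(rng.integers(10, 41)))
        )
        flank_c = "".join(
            str(rng.choice(list(AMINO_ACIDS))) for _ in range(int(rng.integers(10, 41)))
        )
        protein_seq = flank_n + domain + flank_c
        domain_start = len(flank_n) + 1
        domain_end = domain_start + len(domain) - 1

        if rng.random() < spec.scaffold_fraction:
            chromosome, subgenome = f"scaffold_{i + 1}", "none"
        else:
            subgenome = _weighted_choice(rng, subs, sub_weights)
            chromosome = f"{int(rng.integers(1, 8))}{subgenome}"
        strand = "+" if rng.random() < 0.5 else "-"

        # gene model: back-translate, cut introns at blueprint offsets
        cds_nt = back_translate(protein_seq)
        dom_cds_start = 3 * (domain_start - 1) + 1
        cuts = []
        signature = []
        for codon, phase in blueprint:
            mapped = _map_canonical_codon(codon, loop_len)
            d = 3 * mapped if phase == 0 else 3 * (mapped - 1) + phase
            cuts.append(dom_cds_start - 1 + d)
            signature.append((mapped, phase))
        cuts = sorted(set(cuts))
        segments = []
        prev = 0
        for c in cuts:
            segments.append(c - prev)
            prev = c
        segments.append(len(cds_nt) - prev)
        intron_lengths = [int(rng.integers(60, 301)) for _ in cuts]

        span = sum(segments) + sum(intron_lengths)
        gene_start = chrom_cursor.get(chromosome, 1)
        chrom_cursor[chromosome] = gene_start + span + 5000

        exons_plus = []
        pos = gene_start
        for j, seg in enumerate(segments):
            exons_plus.append((pos, pos + seg - 1))
            pos += seg
            if j < len(intron_lengths):
                pos += intron_lengths[j]
        if strand == "-":
            flip_end = gene_start + span - 1

            def flip(x: int) -> int:
                return gene_start + flip_end - x

            exon_ivs = [(flip(e), flip(s)) for s, e in exons_plus]
        else:
            exon_ivs = exons_plus

        cds_ivs = []
        cumulative = 0
        for s, e in exon_ivs:
            frame = (3 - cumulative % 3) % 3
            cds_ivs.append((s, e, frame))
            cumulative += e - s + 1
        model = GeneModel(
            gene_id=gene_id,
            transcript_id=transcript_id,
            strand=strand,
            chromosome=chromosome,
            exons=exon_ivs,
            cds=cds_ivs,
        )
        model.validate()
        genes.append(model)
        cds_seqs[transcript_id] = cds_nt
        proteins.append(
            ProteinRecord(
                id=gene_id,
                sequence=protein_seq,
                species=species,
                chromosome=chromosome,
                subgenome=subgenome,
            )
        )
        truth_rows.append(
            {
                "gene_id": gene_id,
                "transcript_id": transcript_id,
                "species": species,
                "chromosome": chromosome,
                "subgenome": subgenome,
                "domain_start": domain_start,
                "domain_end": domain_end,
                "loop_length": loop_len,
                "binding_category": category,
                "basic_residue_count": basic_count,
                "intron_signature": signature_string(signature),
                "expression_class": expr_class,
            }
        )
    truth = pd.DataFrame(truth_rows)
    return FamilyData(proteins=proteins, genes=genes, cds=cds_seqs, truth=truth, spec=spec)


def signature_string(signature: list[tuple[int, int]]) -> str:
    return ",".join(f"{codon}:{phase}" for codon, phase in signature) if signature else "-"


def write_family(data: FamilyData, out_dir) -> None:
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(data.proteins, out / "proteins.fasta")
    write_gtf(data.genes, out / "genes.gtf")
    write_nucleotide_fasta(data.cds, out / "cds.fasta")
    data.truth.to_csv(out / "truth.tsv", sep="\t", index=False)


# --------------------------------------------------------------------------
# Expression


def generate_expression(
    truth: pd.DataFrame,
    n_samples_per_tissue: int = 3,
    tissues: tuple[str, ...] = ("root", "leaf", "spike"),
    fold_changes: dict[str, float] | None = None,
    dispersion: float = 0.25,
    seed: int = 0,
):
    """Expression matrix plus a generated differential-expression table.

    Tissue-specific genes exceed 10 units only in their own tissue, silent
    genes stay below 5 everywhere, broad genes clear 10 in every tissue.
    The DE table carries planted log2 fold changes plus gaussian noise of
    scale ``dispersion`` and adjusted-p placeholders consistent with the
    effect (well below 0.05 for regulated genes, well above for null genes).
    Returns (ExpressionMatrix, de_stats DataFrame, truth with planted fc).
    """
    from .report import ExpressionMatrix

    if not tissues:
        raise ValueError("at least one tissue is required")
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    fold_changes = fold_changes if fold_changes is not None else {"drought": 2.0}
    for cls in truth["expression_class"]:
        if cls.startswith("tissue-specific:") and cls.split(":", 1)[1] not in tissues:
            raise ValueError(f"truth tissue {cls.split(':', 1)[1]!r} not in declared tissues")

    samples = [f"{t}_rep{r + 1}" for t in tissues for r in range(n_samples_per_tissue)]
    sample_tissue = {s: s.rsplit("_rep", 1)[0] for s in samples}
    values = np.zeros((len(truth), len(samples)))
    truth_out = truth.copy()
    de_rows = []
    for idx, row in enumerate(truth.itertuples(index=False)):
        rng = np.random.default_rng([seed, 7919, idx])
        cls = row.expression_class
        for j, sample in enumerate(samples):
            tissue = sample_tissue[sample]
            if cls == "silent":
                v = min(rng.lognormal(np.log(0.5), 0.5), 4.0)
            elif cls == "broad":
                v = max(rng.lognormal(np.log(50.0), 0.4), 12.0)
            else:  # tissue-specific
                own = cls.split(":", 1)[1]
                if tissue == own:
                    v = max(rng.lognormal(np.log(100.0), 0.4), 12.0)
                else:
                    v = min(rng.lognormal(np.log(1.0), 0.5), 8.0)
            values[idx, j] = round(v, 3)
        for contrast, magnitude in fold_changes.items():
            if cls != "silent" and rng.random() < 0.3:
                true_fc = float(magnitude) * (1 if rng.random() < 0.5 else -1)
            else:
                true_fc = 0.0
            truth_out.loc[idx, f"log2fc_{contrast}"] = true_fc
            observed = true_fc + rng.normal(0.0, dispersion)
            padj = rng.uniform(1e-8, 0.01) if true_fc != 0 else rng.uniform(0.1, 1.0)
            de_rows.append(
                {
                    "gene": row.gene_id,
                    "contrast": contrast,
                    "log2fc": round(float(observed), 4),
                    "padj": round(float(padj), 6),
                }
            )
    matrix = pd.DataFrame(values, index=list(truth["gene_id"]), columns=samples)
    matrix.index.name = "gene"
    em = ExpressionMatrix(values=matrix, unit="TPM", sample_tissue=sample_tissue)
    return em, pd.DataFrame(de_rows), truth_out


# --------------------------------------------------------------------------
# Recovery scoring (generator truth vs pipeline output)


def score_recovery(data: FamilyData, scanner: ConsensusDomainScanner) -> dict[str, float]:
    """Run scan + classify + intron mapping and compare against truth.

    Returns fractions over all genes: located (hit accepted at the planted
    offset), category agreement, intron-signature agreement.
    """
    hits = scanner.predict(data.proteins)
    gene_by_id = {g.gene_id: g for g in data.genes}
    truth_by_id = data.truth.set_index("gene_id")
    located = categories = signatures = 0
    n = len(data.proteins)
    for protein, hit in zip(data.proteins, hits):
        truth = truth_by_id.loc[protein.id]
        if hit is None or not hit.accepted:
            continue
        if hit.start == truth["domain_start"] and hit.end == truth["domain_end"]:
            located += 1
        call = classify_binding(
            hit.domain_sequence(protein.sequence),
            scanner.profile_.region_template,
            protein.id,
        )
        if call.category == truth["binding_category"]:
            categories += 1
        events = map_introns_to_domain(gene_by_id[protein.id], hit)
        recovered = signature_string([(e.domain_codon, e.phase) for e in events])
        if recovered == truth["intron_signature"]:
            signatures += 1
    return {
        "located": located / n,
        "category": categories / n,
        "signature": signatures / n,
    }
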