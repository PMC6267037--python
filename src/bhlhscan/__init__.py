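"""bhlhscan: consensus-based characterization of plant bHLH gene families.

The toolkit locates ~60-aa basic helix-loop-helix domains by counting
mismatches against a seed-alignment consensus (accepting up to a fixed
mismatch budget), classifies each domain's DNA-binding category from the
basic-region residue rules (>=5 basic residues; Glu-13/Arg-16 for E-box,
His/Lys-9 + Arg-17 for G-box), maps intron positions and phases into domain
coordinates to build a pattern taxonomy, and summarises family composition,
conservation and expression filters. A synthetic family generator with full
ground truth makes every stage testable end to end.
"""

from importlib import resources

from .io import (
    AlignmentBlock,
    GeneModel,
    ProteinRecord,
    read_alignment,
    read_fasta,
    read_gtf,
    write_fasta,
    write_gtf,
    write_table,
)
from .scan import (
    ConsensusDomainScanner,
    ConsensusProfile,
    DomainHit,
    RegionTemplate,
    accept_candidate,
    build_consensus,
    domain_length_distribution,
    locate_domain,
    loop_length_distribution,
)
from .binding import (
    BindingCall,
    BindingRuleClassifier,
    classify_binding,
    count_basic_residues,
    derive_aggregates,
    tabulate_categories,
)
from .conservation import (
    column_conservation,
    conserved_positions,
    region_conservation_summary,
)
from .introns import (
    IntronEvent,
    IntronPattern,
    IntronPatternRegistry,
    assign_pattern,
    domain_cds_interval,
    gene_structure_stats,
    map_introns_to_domain,
    pattern_distribution,
)
from .report import (
    DEStatsTable,
    ExpressionMatrix,
    assemble_report,
    chromosome_distribution,
    expression_filter,
    genome_fraction,
    select_degs,
    select_representative,
)
from .simulate import (
    FamilyData,
    FamilySpec,
    generate_expression,
    generate_family,
    score_recovery,
    toy_seed_alignment,
)

__version__ = "0.1.0"


def load_seed_alignment() -> AlignmentBlock:
    """The packaged toy seed alignment (8 rows x 60 columns). Users may
    substitute any aligned domain set of their own."""
    path = resources.files("bhlhscan").joinpath("data/seed_bhlh_alignment.fasta")
    with resources.as_file(path) as p:
        return read_alignment(p)
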