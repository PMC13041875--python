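import pytest

from annoconcord import SimConfig, generate_annotation_table
from annoconcord.agreement_core import Source


def gene_level_protein_sets(records):
    """Identity protein mapping: pool a record's namespaced gene ids,
    per (tool, gene_model), treating the identifier string as the protein."""
    out: dict[str, dict[Source, frozenset[str]]] = {}
    for rec in records:
        per_source: dict[Source, set[str]] = {}
        for (tool, model, _role), ids in rec.gene_calls.items():
            per_source.setdefault((tool, model), set()).update(
                gid for _ns, gid in ids
            )
        out[rec.variant_id] = {k: frozenset(v) for k, v in per_source.items()}
    return out


@pytest.fixture(scope="session")
def small_records():
    """300 variants under the default study conditions (no crosswalk noise)."""
    cfg = SimConfig(n_variants=300, seed=11, frac_deprecated=0.0,
                    frac_noncoding=0.0)
    return generate_annotation_table(cfg)
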