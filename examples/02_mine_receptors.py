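"""Mine receptor coding sequences from raw transcripts.

ORF extraction under a receptor gene model, DNA-level dedupe, the 30%
group-identity filter, and best-hit annotation against a reference
repertoire — shown on a small simulated transcript set.
"""

import tempfile

from v1r_clade_evo.config import PipelineConfig
from v1r_clade_evo.pipeline import stage_mine, stage_simulate
from v1r_clade_evo import io

with tempfile.TemporaryDirectory() as tmp:
    cfg = PipelineConfig(out_dir=f"{tmp}/run", seed=7, simulate={"n_root_genes": 8})
    stage_simulate(cfg)
    stage_mine(cfg)

    hits = io.read_tsv(f"{cfg.out_dir}/hits.tsv")
    ann = io.read_tsv(f"{cfg.out_dir}/annotations.tsv")
    print(f"transcripts annotated: {len(ann)}")
    print("example best hits (query -> reference gene, % identity):")
    for _, row in hits.head(5).iterrows():
        print(f"  {row['query']:24s} -> {row['reference']:10s} {row['identity']}%")
    suffixed = ann[ann["annotation"].str.contains(r"\.", regex=True)]
    print(f"same-gene transcripts disambiguated with .n suffixes: {len(suffixed)}")
# Identity is near 100% for same-gene transcripts and drops with phylogenetic
# distance from the reference; sub-30% candidates would have been filtered.
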