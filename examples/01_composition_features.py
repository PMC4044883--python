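"""Compute sequence-composition features from FASTA and build the
48-column feature table.

The 17 composition features (16 overlapping dinucleotide frequencies and
the G+C fraction) are computed natively; the 31 folding/thermodynamic
features come from an external RNA-structure engine and are merged by id
(here: synthetic stand-in numbers, labelled as such).
"""

import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from hairpinldr import (
    THERMODYNAMIC_FEATURES,
    composition_features,
    merge_external_features,
    read_fasta,
)

fasta = """\
>hsa-let-7a-like
UGGGAUGAGGUAGUAGGUUGUAUAGUUUUAGGGUCACACCCACCACUGGGAGAUAACUAUACAAUCUACUGUCUUUCCUA
>pseudo-hairpin-1
GCAUGCAUGCAUGCGCGCGCAUAUAUGCGCGCAUGCAUGGCAUGCAUGCAUGCGCGCAUAUAUGCGCAUGCAUGCA
"""
with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "hairpins.fa"
    path.write_text(fasta)
    records = read_fasta(path)

table = composition_features(records)
print("composition features per record (first 4 columns + GC ratio):")
print(table.frame[["freq_AA", "freq_AC", "freq_AG", "freq_AU", "GC_ratio"]].round(4))
# each row of the 16 dinucleotide frequencies sums to 1; GC_ratio is the
# G+C fraction of the sequence

rng = np.random.default_rng(0)
external = pd.DataFrame(  # synthetic stand-in for folding-engine output
    rng.normal(size=(len(records), 31)),
    index=table.ids,
    columns=list(THERMODYNAMIC_FEATURES),
)
full = merge_external_features(table, external)
print(f"\nmerged table: {full.n_features} feature columns "
      f"(17 composition + 31 thermodynamic) for {len(full)} records")
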