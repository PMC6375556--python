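#!/usr/bin/env python
"""Classify high-functional-impact variants on the filtered set and compute
callable bases and mutation burden in both reporting modes.

The 200 kb simulated depth track is a thinned stand-in for a whole exome, so
the burden denominator extrapolates its callable fraction to a nominal 36 Mb
target territory.

Finding: roughly half the gene-analysis candidates are HFI (by construction of
the generator's verdict model), and the non-synonymous burden is, necessarily,
no larger than the all-variant burden.
"""

import json
from pathlib import Path

from neoexome import filters as F
from neoexome import io_formats as io
from neoexome.burden import callable_bases, mutation_burden
from neoexome.impact import hfi_gene_list, impact_table, select_nonsynonymous

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    records = io.read_variants(RESULTS / "simulated" / "tumour_variants.tsv")
    audit = F.filter_variants(records)
    kept = F.apply_audit(records, audit)

    genic = F.restrict_for_gene_analysis(select_nonsynonymous(kept))
    table = impact_table(genic)
    table.to_csv(RESULTS / "impact.tsv", sep="\t", index=False)
    genes = hfi_gene_list(genic)
    (RESULTS / "hfi_genes.json").write_text(json.dumps(genes, indent=2))

    track = io.read_depth_track(RESULTS / "simulated" / "depth_track.bed")
    bases = callable_bases(track)
    # extrapolate the track's callable fraction to a nominal 36 Mb exome
    exome_bases = int(36_000_000 * bases / track.length)
    burden = mutation_burden(kept, exome_bases)
    (RESULTS / "burden.json").write_text(json.dumps(burden.__dict__, indent=2) + "\n")

    r_all, r_nonsyn = burden.rounded()
    print(f"HFI: {int(table['hfi'].sum())} of {len(table)} gene-analysis candidates, "
          f"{len(genes)} distinct genes")
    print(f"callable: {bases} of {track.length} track bases "
          f"({100 * bases / track.length:.1f}%), {exome_bases / 1e6:.1f} Mb extrapolated")
    print(f"burden: {r_all}/Mb all variants, {r_nonsyn}/Mb non-synonymous")


if __name__ == "__main__":
    main()
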