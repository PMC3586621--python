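#!/usr/bin/env python
"""Summary statistics for a user-supplied reference alignment.

The deposited reference sequences are a public-database download and are
not bundled with the package.  Given that alignment as FASTA, this script
recomputes the quantities reported for it: haplotype count, variable and
parsimony-informative site counts, pooled base frequencies, and the
chi-square test of base-frequency homogeneity.  With an additional
established-set FASTA it also reports the divergence range between the
two sets.  Output is JSON on stdout.

Example:
    python scripts/validate_reference.py --alignment refs.fasta \
        [--established established.fasta] [--prefix MAF]
"""

from __future__ import annotations

import argparse
import json


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--alignment", required=True, help="Aligned FASTA.")
    parser.add_argument("--established", default=None,
                        help="Optional FASTA of established-range haplotypes "
                             "for a divergence-band report.")
    parser.add_argument("--prefix", default="H", help="Haplotype label prefix.")
    args = parser.parse_args()

    import numpy as np

    from skinktrace.alignment import collapse_haplotypes, read_alignment
    from skinktrace.distances import (
        base_composition,
        composition_homogeneity_test,
        count_site_patterns,
        site_summary,
        trn_distance,
    )

    aln = read_alignment(args.alignment)
    table = collapse_haplotypes(aln, args.prefix)
    sites = site_summary(aln)
    comp = base_composition(aln)
    chi = composition_homogeneity_test(aln)

    out = {
        "n_sequences": len(aln),
        "alignment_length": aln.length,
        "n_haplotypes": len(table),
        "variable_sites": sites.variable_sites,
        "variable_proportion": round(sites.variable_proportion, 4),
        "parsimony_informative_sites": sites.parsimony_informative_sites,
        "parsimony_informative_proportion": round(
            sites.parsimony_informative_proportion, 4
        ),
        "base_frequencies": {k: round(v, 3) for k, v in comp.as_dict().items()},
        "chi_square": round(chi.statistic, 2),
        "df": chi.df,
        "p_value": round(chi.p_value, 4),
    }

    if args.established:
        est = read_alignment(args.established)
        dists = []
        for _, q in est:
            for _, r in aln:
                d, flag = trn_distance(count_site_patterns(q, r), comp)
                if flag == "ok" and d > 0:
                    dists.append(d)
        if dists:
            out["divergence_to_established"] = {
                "min": round(float(np.min(dists)), 4),
                "max": round(float(np.max(dists)), 4),
            }

    print(json.dumps(out, indent=2))


if __name__ == "__main__":
    main()
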