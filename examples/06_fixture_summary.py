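"""Summarize the packaged 26-row DMP table.

The package ships a fixture transcribing a published table of 26
differentially methylated CpGs in HPA-axis genes (former PICU patients vs
healthy children).  ``summarize_dmps`` reproduces the study-level summary
statistics directly from the table.
"""

from hpameth.dmp import summarize_dmps
from hpameth.io import load_table2_fixture

fixture = load_table2_fixture()
s = summarize_dmps(fixture)

print(f"{s['n_dmps']} DMPs across {s['n_genes']} genes; "
      f"{s['pct_hypo']}% hypomethylated in patients")
print(f"absolute group difference in mean beta: "
      f"mean {s['mean_abs_diff_pct']}%, SD {s['sd_abs_diff_pct']}%, "
      f"max {s['max_abs_diff_pct']}%")
fk = s["per_gene"]["FKBP5"]
print(f"FKBP5: {fk['n_dmps']} DMPs = {fk['pct_of_selected']}% of its "
      f"{fk['n_selected_cpgs']} selected CpGs")
print(f"interaction rows at p <= 0.05: age {s['n_age_interaction']}, "
      f"sex {s['n_sex_interaction']}")
print(f"rows associated with glucocorticoid treatment: {s['n_gc_associated']} "
      f"(of which {int((fixture[fixture['gene'] == 'FKBP5']['p_gc'] <= 0.05).sum())} in FKBP5)")
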