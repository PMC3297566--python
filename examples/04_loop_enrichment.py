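"""Paralog-weighted D/E enrichment in loop columns of a family alignment.

Generates a synthetic PDZ-family-like alignment with planted paralog
groups (>= 50% identity within a group) and a planted enrichment of
negatively charged residues (D/E) in the loop columns.  Sequences are
grouped by single-linkage at 50% identity, each member of a group of
size g weighted 1/g, and the enrichment is tested with a one-sided
Fisher exact test on the unweighted counts.
"""

from pdznet import group_paralogs, loop_enrichment
from pdznet import synthetic

spec = synthetic.MSAGeneratorSpec(
    group_sizes=(5, 4, 3, 3, 2, 2) + (1,) * 24,
    loop_enrichment_factor=2.0,
    seed=17,
)
seqs, true_groups, loop_cols = synthetic.gen_msa(spec)
wmsa = group_paralogs(seqs, identity_cutoff=0.5)

print(f"alignment: {len(seqs)} sequences x {spec.n_columns} columns, "
      f"loop columns {loop_cols[0]}..{loop_cols[-1]}")
print(f"paralog groups recovered: {len(wmsa.groups)} "
      f"(planted: {len(true_groups)})")
sizes = sorted((len(g) for g in wmsa.groups), reverse=True)
print(f"group sizes: {sizes}; a member of the group of {sizes[0]} "
      f"weighs {wmsa.weights[sorted(max(wmsa.groups, key=len))[0]]:.3f}")

res = loop_enrichment(wmsa, loop_cols, residue_class="DE")
print(f"\nweighted D/E frequency: whole domain {100 * res.freq_overall:.1f}%, "
      f"loop columns {100 * res.freq_loop:.1f}%")
print(f"2x2 counts [[D/E loop, other loop], [D/E rest, other rest]]: "
      f"{res.table.tolist()}")
print(f"one-sided Fisher P for loop over-representation: {res.p_value:.2e}")
print("\nA small P means the loop carries more negative residues than the")
print("rest of the domain can explain by chance; the weighted frequencies")
print("quantify the effect while discounting redundant paralogs.")
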