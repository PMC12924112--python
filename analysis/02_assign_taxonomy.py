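"""Assign consensus taxonomy to the simulated OTUs and check it against the
planted source lineages.

Writes results/assignments.tsv and prints the assignment-depth profile plus
the agreement rate with the planted phylum per OTU.
"""

from pathlib import Path
from collections import Counter

from benthos16s.io_model import read_hits, read_lineage_map, write_assignments
from benthos16s.taxonomy import assign_taxonomy, group_hits_by_query
from benthos16s.synthetic import gen_survey

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    data = ROOT / "data"
    lineage_map = read_lineage_map(data / "lineages.tsv")
    hits = read_hits(data / "hits.tsv", lineage_map)
    assignments = assign_taxonomy(group_hits_by_query(hits))
    write_assignments(assignments, ROOT / "assignments.tsv")

    depth_profile = Counter(a.assigned_rank for a in assignments)
    print("assignment depth profile:", dict(depth_profile))

    truth = gen_survey(seed=7)["truth"]
    by_otu = {a.otu_id: a for a in assignments}
    agree = total = 0
    for otu, phylum in truth.phylum_of_otu.items():
        a = by_otu.get(otu)
        if a is None or a.lineage.depth < 2:
            continue
        total += 1
        agree += a.lineage.names[1] == phylum
    print(f"planted-phylum agreement among phylum-assigned OTUs: {agree}/{total}")


if __name__ == "__main__":
    main()
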