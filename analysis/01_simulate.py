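"""Generate the default synthetic benthic survey and write its inputs.

Emits the hit table, reference lineages, OTU count table with sample roles,
environmental metadata, and the planted ground truth under results/data/.
"""

import json
from pathlib import Path

from benthos16s.io_model import (
    write_env_table,
    write_hits,
    write_lineage_map,
    write_otu_table,
)
from benthos16s.synthetic import gen_survey

SEED = 7
OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    survey = gen_survey(seed=SEED)
    write_lineage_map(survey["lineage_map"], OUT / "lineages.tsv")
    write_hits(
        [h for hs in survey["hits_by_otu"].values() for h in hs], OUT / "hits.tsv"
    )
    write_otu_table(survey["table"], OUT / "otu.tsv", OUT / "roles.tsv")
    write_env_table(survey["env"], OUT / "meta.csv")
    with open(OUT / "truth.json", "w") as fh:
        json.dump(survey["truth"].to_dict(), fh, indent=2, sort_keys=True)
    t = survey["table"]
    print(
        f"survey: {len(t.otu_ids)} OTUs x {len(t.true_sample_ids)} samples "
        f"(+{len(t.control_ids)} blanks), "
        f"{len(survey['hits_by_otu'])} OTUs with hits -> {OUT}"
    )


if __name__ == "__main__":
    main()
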