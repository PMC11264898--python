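"""Full pipeline into a SQLite store, then query it: search bar, region
comparison, Circos rings, portable archive.

Runs every stage on a synthetic panel, persists the results, and exercises
the query surface a visualization layer would consume.
"""

import tempfile
from pathlib import Path

from orthopan import store as st
from orthopan.synthetic import FixtureConfig, generate_fixture

with tempfile.TemporaryDirectory() as td:
    work = Path(td)
    paths, truth = generate_fixture(FixtureConfig(seed=2), work / "fx")
    store = st.run_pipeline(
        work / "fx", work / "results.db",
        orthogroup_table=work / "fx" / "orthogroups.tsv",
        ko_table=work / "fx" / "ko.tsv",
        cog_table=work / "fx" / "cog.tsv",
        modules_table=work / "fx" / "modules.tsv",
        max_missing=1,
    )

    print("run metadata:", {k: v for k, v in sorted(store.metadata().items())
                            if k.startswith("param_")})

    # search bar: wildcards and boolean operators over all gene fields
    query = 'product:"family 3 protein" AND NOT genome:g1'
    print(f"\nsearch {query!r} ->")
    print(store.search(query))

    # region comparison around a core gene
    anchor = truth.genes[0]
    rc = store.region_comparison(anchor.genome_id, anchor.locus_tag,
                                 window_bp=2500)
    print(f"region comparison around {anchor.locus_tag}: "
          f"{len(rc.tracks)} tracks, {len(rc.links)} ortholog links, "
          f"{len(rc.notices)} genomes without ortholog")
    worst = min((ident for *_x, ident in rc.links), default=None)
    print(f"  lowest link identity: {worst:.1f}%" if worst is not None else "")

    # Circos rings for genome g1 against the rest
    ts = store.circos_tracks("g1")
    present = sum(1 for v in ts.presence[sorted(ts.presence)[0]] if v is not None)
    print(f"circos tracks: {len(ts.orf_order)} reference ORFs, "
          f"GC ring mean {sum(ts.gc_per_orf)/len(ts.gc_per_orf):.1f}%, "
          f"{present} ORFs with a homolog in {sorted(ts.presence)[0]}")

    # portable archive round trip
    arc = st.export_archive(store, work / "run.tar.gz")
    restored = st.import_archive(arc, work / "restored.db")
    same = store.table_rowsets() == restored.table_rowsets()
    print(f"\narchive exported ({arc.stat().st_size} bytes), re-imported, "
          f"contents identical: {same}")
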