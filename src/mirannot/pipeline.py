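"""End-to-end annotation pipeline with file-backed, resumable stages.

Each stage reads its inputs from the output directory of the previous
stages (running them first when missing), writes plain-text outputs, and
is skipped when its outputs already exist unless forced — so stages can
be run individually from the CLI, and a completed run is idempotent.
The report stage enforces the internal consistency of the final counts
(conserved = high + low, total = conserved + novel, context categories
sum to total) and fails hard when an intermediate has been corrupted.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import context as ctx
from . import curation, discovery, homology, isomir, pirna
from .align import ReadAlignment, SeedIndex, align_all
from .config import PipelineConfig
from .discovery import HairpinCandidate, extract_precursor
from .fold import nussinov_fold, validate_hairpin
from .intervals import GenomicInterval
from .io import (
    CollapsedRead,
    read_collapsed,
    read_fasta,
    read_gff3,
    read_gtf,
    to_bed,
    to_gff3,
    write_collapsed,
    write_fasta,
)
from .preprocess import preprocess_library

STAGE_ORDER = (
    "preprocess",
    "discover",
    "homology",
    "curate",
    "context",
    "mirtron",
    "isomir",
    "pirna",
    "report",
)

STAGE_OUTPUTS = {
    "preprocess": ["library_stats.tsv"],
    "discover": ["candidates.gff3", "candidates.fa"],
    "homology": ["conserved_loci.tsv"],
    "curate": [
        "loci.tsv",
        "hairpins.fa",
        "mature_calls.tsv",
        "expression_rpm.tsv",
        "arm_counts.tsv",
        "switching.tsv",
        "five_prime_histogram.tsv",
        "profiles.tsv",
    ],
    "context": ["context.tsv"],
    "mirtron": ["mirtrons.tsv"],
    "isomir": ["isomir_counts.tsv"],
    "pirna": ["pirna_clusters.tsv", "pirna_merged.bed"],
    "report": ["summary.tsv", "annotation.gff3", "manifest.json"],
}

_ALN_COLS = ["read_id", "target", "start", "end", "strand", "mismatches", "length", "count", "sequence"]


class ConsistencyError(RuntimeError):
    """Final report counts violate an internal conservation invariant."""


class Pipeline:
    def __init__(self, config: PipelineConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self._cache: dict[str, object] = {}

    # ------------------------------------------------------------------ io
    def path(self, name: str) -> Path:
        return self.outdir / name

    def stage_done(self, stage: str) -> bool:
        return all(self.path(n).exists() for n in STAGE_OUTPUTS[stage])

    def _require(self, stage: str) -> None:
        if not self.stage_done(stage):
            self.run(stage)

    # -------------------------------------------------------------- inputs
    @property
    def genome(self) -> dict[str, str]:
        if "genome" not in self._cache:
            if not Path(self.config.genome).exists():
                raise FileNotFoundError(f"genome FASTA not found: {self.config.genome}")
            self._cache["genome"] = read_fasta(self.config.genome)
        return self._cache["genome"]  # type: ignore[return-value]

    @property
    def genome_index(self) -> SeedIndex:
        if "genome_index" not in self._cache:
            self._cache["genome_index"] = SeedIndex(self.genome)
        return self._cache["genome_index"]  # type: ignore[return-value]

    @property
    def gene_models(self):
        if "gene_models" not in self._cache:
            self._cache["gene_models"] = read_gtf(self.config.gtf)
        return self._cache["gene_models"]

    @property
    def existing_annotation(self) -> list[GenomicInterval]:
        if "existing" not in self._cache:
            path = self.config.existing_annotation
            records = read_gff3(path) if path and Path(path).exists() else []
            self._cache["existing"] = [iv for iv, _t, _a in records]
        return self._cache["existing"]  # type: ignore[return-value]

    def tissues(self) -> list[str]:
        return sorted(self.config.reads)

    # --------------------------------------------------- cached stage data
    def processed_reads(self, tissue: str) -> list[CollapsedRead]:
        key = f"reads:{tissue}"
        if key not in self._cache:
            self._require("preprocess")
            self._cache[key] = read_collapsed(self.path(f"processed/{tissue}.fa"))
        return self._cache[key]  # type: ignore[return-value]

    def alignments(self, tissue: str) -> list[ReadAlignment]:
        key = f"aln:{tissue}"
        if key not in self._cache:
            self._require("preprocess")
            df = pd.read_csv(self.path(f"alignments/{tissue}.tsv"), sep="\t")
            self._cache[key] = [
                ReadAlignment(
                    str(r.read_id), str(r.target), int(r.start), str(r.strand),
                    int(r.mismatches), int(r.length), int(r.count), str(r.sequence),
                )
                for r in df.itertuples()
            ]
        return self._cache[key]  # type: ignore[return-value]

    def combined_alignments(self) -> list[ReadAlignment]:
        if "aln:combined" not in self._cache:
            combined: list[ReadAlignment] = []
            for tissue in self.tissues():
                combined.extend(self.alignments(tissue))
            self._cache["aln:combined"] = combined
        return self._cache["aln:combined"]  # type: ignore[return-value]

    def library_stats(self) -> pd.DataFrame:
        self._require("preprocess")
        return pd.read_csv(self.path("library_stats.tsv"), sep="\t", index_col="tissue")

    def final_loci(self) -> pd.DataFrame:
        self._require("curate")
        return pd.read_csv(self.path("loci.tsv"), sep="\t")

    def final_intervals(self) -> list[tuple[str, GenomicInterval]]:
        return [
            (row.hairpin_id, GenomicInterval(row.chrom, int(row.start), int(row.end), row.strand))
            for row in self.final_loci().itertuples()
        ]

    # --------------------------------------------------------------- runs
    def run(self, stage: str, force: bool = False) -> bool:
        """Run one stage (prerequisites first); returns False when skipped."""
        if stage not in STAGE_ORDER:
            raise ValueError(f"unknown stage {stage!r}")
        for dep in STAGE_ORDER[: STAGE_ORDER.index(stage)]:
            if not self.stage_done(dep):
                self.run(dep)
        if self.stage_done(stage) and not force:
            return False
        self.outdir.mkdir(parents=True, exist_ok=True)
        getattr(self, f"_stage_{stage}")()
        return True

    def run_all(self, force: bool = False) -> "Pipeline":
        for stage in STAGE_ORDER:
            self.run(stage, force=force)
        return self

    # ------------------------------------------------------------- stages
    def _stage_preprocess(self) -> None:
        cfg = self.config
        missing = [p for p in [cfg.genome, *cfg.reads.values()] if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input file(s): {', '.join(missing)}")
        (self.outdir / "processed").mkdir(exist_ok=True)
        (self.outdir / "alignments").mkdir(exist_ok=True)
        rows = []
        for tissue in self.tissues():
            raw = read_collapsed(cfg.reads[tissue])
            kept, stats = preprocess_library(
                tissue, raw, cfg.adapter or None, cfg.min_read_len, cfg.adapter_min_overlap
            )
            write_collapsed(kept, self.path(f"processed/{tissue}.fa"))
            alns = align_all(kept, self.genome_index, 0, "both") if kept else []
            matched_ids = {a.read_id for a in alns}
            stats.genome_matching = sum(r.count for r in kept if r.id in matched_ids)
            stats.validate()
            pd.DataFrame(
                [
                    {
                        "read_id": a.read_id, "target": a.target, "start": a.start,
                        "end": a.end, "strand": a.strand, "mismatches": a.mismatches,
                        "length": a.length, "count": a.count, "sequence": a.sequence,
                    }
                    for a in alns
                ],
                columns=_ALN_COLS,
            ).to_csv(self.path(f"alignments/{tissue}.tsv"), sep="\t", index=False)
            rows.append(
                {
                    "tissue": tissue,
                    "total_reads": stats.total_reads,
                    "trimmed_ge_min": stats.trimmed_ge_min,
                    "genome_matching": stats.genome_matching,
                    "length_histogram": json.dumps(stats.length_histogram),
                }
            )
        pd.DataFrame(rows).to_csv(self.path("library_stats.tsv"), sep="\t", index=False)

    def _stage_discover(self) -> None:
        cfg = self.config
        combined = self.combined_alignments()
        clusters = discovery.cluster_read_stacks(combined, cfg.cluster_max_gap)
        clusters = [c for c in clusters if c.count >= cfg.discovery_min_cluster_count]
        windows = [
            w
            for c in clusters
            for w in discovery.excise_precursors(
                c, self.genome, cfg.excise_flank, cfg.precursor_max_len
            )
        ]
        candidates = discovery.propose_candidates(
            windows,
            combined,
            self.genome,
            cfg.precursor_min_len,
            cfg.precursor_max_len,
            cfg.discovery_min_cluster_count,
            cfg.min_stem_pairs,
            cfg.min_loop,
        )
        records = [
            (c.locus, "miRNA_candidate", {"ID": c.id, "source_stage": c.source})
            for c in candidates
        ]
        self.path("candidates.gff3").write_text(to_gff3(records))
        write_fasta({c.id: c.precursor_seq for c in candidates}, self.path("candidates.fa"))

    def discovery_candidates(self) -> list[HairpinCandidate]:
        if "candidates" not in self._cache:
            self._require("discover")
            seqs = read_fasta(self.path("candidates.fa"))
            cands = []
            for iv, _t, attrs in read_gff3(self.path("candidates.gff3")):
                seq = seqs[attrs["ID"]]
                cands.append(
                    HairpinCandidate(iv, seq, nussinov_fold(seq, self.config.min_loop), "DISCOVERY")
                )
            self._cache["candidates"] = cands
        return self._cache["candidates"]  # type: ignore[return-value]

    def _stage_homology(self) -> None:
        cfg = self.config
        ref_hairpins = read_fasta(cfg.reference_hairpins)
        ref_matures = read_fasta(cfg.reference_matures) if cfg.reference_matures else {}
        hits = homology.map_hairpins(
            ref_hairpins, self.genome_index, cfg.homology_min_len, cfg.homology_min_identity
        )
        confirmed = []
        for hit in hits:
            matures = [s for mid, s in ref_matures.items() if mid.startswith(hit.query_id)]
            hit = homology.confirm_mature(hit, matures, self.genome, cfg.mature_max_mismatch)
            if hit.mature_confirmed:
                confirmed.append(hit)
        # de-duplicate overlapping confirmed hits: best identity represents a locus
        confirmed.sort(key=lambda h: (-h.identity, h.query_id))
        kept: list[homology.HomologyHit] = []
        for hit in confirmed:
            if not any(hit.locus.overlaps(k.locus) for k in kept):
                kept.append(hit)
        kept.sort(key=lambda h: h.locus)
        pd.DataFrame(
            [
                {
                    "query_id": h.query_id,
                    "chrom": h.locus.chrom,
                    "start": h.locus.start,
                    "end": h.locus.end,
                    "strand": h.locus.strand,
                    "alignment_length": h.alignment_length,
                    "identity": h.identity,
                    "mature_mismatches": h.mature_mismatches,
                }
                for h in kept
            ],
            columns=[
                "query_id", "chrom", "start", "end", "strand",
                "alignment_length", "identity", "mature_mismatches",
            ],
        ).to_csv(self.path("conserved_loci.tsv"), sep="\t", index=False)

    def conserved_hits(self) -> pd.DataFrame:
        self._require("homology")
        return pd.read_csv(self.path("conserved_loci.tsv"), sep="\t")

    def _stage_curate(self) -> None:
        cfg = self.config
        conserved_df = self.conserved_hits()
        conserved_loci = [
            GenomicInterval(r.chrom, int(r.start), int(r.end), r.strand)
            for r in conserved_df.itertuples()
        ]
        conserved_records = [
            HairpinCandidate(
                iv,
                extract_precursor(self.genome, iv),
                nussinov_fold(extract_precursor(self.genome, iv), cfg.min_loop),
                "HOMOLOGY",
            )
            for iv in conserved_loci
        ]
        split = homology.split_known_novel(
            [c.locus for c in self.discovery_candidates()],
            conserved_loci,
            self.existing_annotation,
        )
        novel_set = {(iv.chrom, iv.start, iv.end, iv.strand) for iv in split["novel"]}
        newly_set = {(iv.chrom, iv.start, iv.end, iv.strand) for iv in split["newly_annotated"]}
        novel_records = [
            c
            for c in self.discovery_candidates()
            if (c.locus.chrom, c.locus.start, c.locus.end, c.locus.strand) in novel_set
        ]

        loci = conserved_records + novel_records
        aln_by_tissue = {t: self.alignments(t) for t in self.tissues()}
        profiles = curation.build_profiles(loci, aln_by_tissue)

        rows, mature_rows, keep = [], [], []
        loop_mid_by_id: dict[str, int] = {}
        for cand in loci:
            agg = curation.aggregate_profile(
                profiles[(cand.id, t)] for t in self.tissues()
            )
            loop_mid = curation.loop_midpoint(cand, cfg.min_stem_pairs)
            loop_mid_by_id[cand.id] = loop_mid
            calls = curation.call_matures(agg, loop_mid)
            two_peak = curation.two_peak_test(
                agg, loop_mid, cfg.peak_window, cfg.peak_min_fraction, cfg.peak_min_count
            )
            arms = curation.split_arms(agg, loop_mid)
            both_arms = bool(arms["5p"]) and bool(arms["3p"])
            c5, c3 = calls["5p"], calls["3p"]
            structure = bool(
                c5
                and c3
                and validate_hairpin(
                    cand.fold,
                    (c5.start, c5.end),
                    (c3.start, c3.end),
                    cfg.validate_min_paired,
                    cfg.loop_overlap_max,
                    cfg.min_stem_pairs,
                )
            )
            record = curation.classify_confidence(cand.id, structure, two_peak, both_arms)
            is_conserved = cand.source == "HOMOLOGY"
            if not is_conserved and record.confidence != "HIGH":
                continue  # novel loci require full support to be reported at all
            keep.append(cand)
            key = (cand.locus.chrom, cand.locus.start, cand.locus.end, cand.locus.strand)
            rows.append(
                {
                    "hairpin_id": cand.id,
                    "chrom": cand.locus.chrom,
                    "start": cand.locus.start,
                    "end": cand.locus.end,
                    "strand": cand.locus.strand,
                    "source": cand.source,
                    "class": "conserved" if is_conserved else "novel",
                    "newly_annotated": is_conserved and key in newly_set,
                    "confidence": record.confidence,
                    "two_peak_pass": record.two_peak_pass,
                    "structure_pass": record.structure_pass,
                    "both_arms_expressed": record.both_arms_expressed,
                }
            )
            for arm in ("5p", "3p"):
                call = calls[arm]
                if call:
                    mature_rows.append(
                        {
                            "hairpin_id": cand.id, "arm": arm, "sequence": call.sequence,
                            "start": call.start, "end": call.end, "support": call.support,
                        }
                    )
        pd.DataFrame(
            rows,
            columns=[
                "hairpin_id", "chrom", "start", "end", "strand", "source", "class",
                "newly_annotated", "confidence", "two_peak_pass", "structure_pass",
                "both_arms_expressed",
            ],
        ).to_csv(self.path("loci.tsv"), sep="\t", index=False)
        pd.DataFrame(
            mature_rows, columns=["hairpin_id", "arm", "sequence", "start", "end", "support"]
        ).to_csv(self.path("mature_calls.tsv"), sep="\t", index=False)
        write_fasta({c.id: c.precursor_seq for c in keep}, self.path("hairpins.fa"))
        write_fasta(
            {f"{r['hairpin_id']}-{r['arm']}": r["sequence"] for r in mature_rows},
            self.path("matures.fa"),
        )

        kept_ids = {c.id for c in keep}
        kept_profiles = {k: v for k, v in profiles.items() if k[0] in kept_ids}
        totals = {
            t: int(self.library_stats().loc[t, "genome_matching"]) for t in self.tissues()
        }
        curation.expression_matrix(kept_profiles, totals).to_csv(
            self.path("expression_rpm.tsv"), sep="\t", index_label="hairpin_id"
        )
        table = curation.arm_abundance_table(kept_profiles, loop_mid_by_id)
        table.to_csv(self.path("arm_counts.tsv"), sep="\t", index=False)
        switching = curation.detect_arm_switching(table, cfg.switching_min_total)
        pd.DataFrame({"hairpin_id": switching}).to_csv(
            self.path("switching.tsv"), sep="\t", index=False
        )
        curation.five_prime_fraction_histogram(table).to_csv(
            self.path("five_prime_histogram.tsv"), sep="\t", index_label="bin"
        )
        prof_rows = []
        for (hid, tissue), prof in sorted(kept_profiles.items()):
            for pos, count in sorted(prof.start_counts.items()):
                prof_rows.append(
                    {"hairpin_id": hid, "tissue": tissue, "position": pos, "start_count": count}
                )
        pd.DataFrame(
            prof_rows, columns=["hairpin_id", "tissue", "position", "start_count"]
        ).to_csv(self.path("profiles.tsv"), sep="\t", index=False)

    def _stage_context(self) -> None:
        feats = ctx.annotation_features(self.gene_models)
        rows = []
        for hid, iv in self.final_intervals():
            label = ctx.classify_locus(iv, feats, self.config.context_min_fraction)
            rows.append(
                {
                    "hairpin_id": hid,
                    "category": label.category,
                    "overlap_fraction": round(label.overlap_fraction, 4),
                    "host_transcript": label.host or "",
                }
            )
        pd.DataFrame(
            rows, columns=["hairpin_id", "category", "overlap_fraction", "host_transcript"]
        ).to_csv(self.path("context.tsv"), sep="\t", index=False)

    def _stage_mirtron(self) -> None:
        cfg = self.config
        introns = [
            iv
            for ivs in ctx.derive_introns(self.gene_models).values()
            for iv in ivs
        ]
        calls = ctx.detect_mirtrons(
            self.final_intervals(),
            introns,
            self.combined_alignments(),
            cfg.mirtron_tail_max,
            cfg.peak_window,
            cfg.peak_min_fraction,
            cfg.peak_min_count,
            (cfg.mirtron_len_min, cfg.mirtron_len_max),
            cfg.mirtron_min_coverage,
        )
        pd.DataFrame(
            [
                {
                    "hairpin_id": c.hairpin_id,
                    "chrom": c.intron.chrom,
                    "intron_start": c.intron.start,
                    "intron_end": c.intron.end,
                    "strand": c.intron.strand,
                    "intron_length": c.intron.length,
                    "intron_coverage": round(c.intron_coverage, 4),
                    "end5_offset": c.end5_offset,
                    "end3_offset": c.end3_offset,
                }
                for c in calls
            ],
            columns=[
                "hairpin_id", "chrom", "intron_start", "intron_end", "strand",
                "intron_length", "intron_coverage", "end5_offset", "end3_offset",
            ],
        ).to_csv(self.path("mirtrons.tsv"), sep="\t", index=False)

    def _stage_isomir(self) -> None:
        matures = pd.read_csv(self.path("mature_calls.tsv"), sep="\t")
        loci = {hid: iv for hid, iv in self.final_intervals()}
        records = []
        for row in matures.itertuples():
            iv = loci[row.hairpin_id]
            if iv.strand == "-":
                mat_iv = GenomicInterval(iv.chrom, iv.end - int(row.end), iv.end - int(row.start), "-")
            else:
                mat_iv = GenomicInterval(iv.chrom, iv.start + int(row.start), iv.start + int(row.end), "+")
            for tissue in self.tissues():
                records.extend(
                    isomir.detect_nta(
                        self.processed_reads(tissue),
                        f"{row.hairpin_id}-{row.arm}",
                        str(row.sequence),
                        mat_iv,
                        self.genome,
                        tissue,
                    )
                )
        table = isomir.isoform_table(records)
        table.to_csv(self.path("isomir_counts.tsv"), sep="\t")

    def _stage_pirna(self) -> None:
        cfg = self.config
        rows = []
        all_clusters = []
        for tissue in self.tissues():
            weighted = pirna.reallocate_counts(self.alignments(tissue), cfg.pirna_window)
            clusters = pirna.call_clusters(
                weighted,
                tissue,
                cfg.pirna_min_size,
                cfg.pirna_min_hits,
                cfg.pirna_min_sig,
                (cfg.pirna_size_min, cfg.pirna_size_max),
                cfg.pirna_min_size_frac,
                cfg.pirna_max_gap,
            )
            all_clusters.extend(clusters)
            for c in clusters:
                rows.append(
                    {
                        "tissue": tissue,
                        "chrom": c.interval.chrom,
                        "start": c.interval.start,
                        "end": c.interval.end,
                        "normalized_hits": round(c.normalized_hits, 2),
                        "n_distinct_seqs": c.n_distinct_seqs,
                        "frac_1t_or_10a": round(c.frac_1t_or_10a, 4),
                        "strand_class": c.strand_class,
                    }
                )
        pd.DataFrame(
            rows,
            columns=[
                "tissue", "chrom", "start", "end", "normalized_hits",
                "n_distinct_seqs", "frac_1t_or_10a", "strand_class",
            ],
        ).to_csv(self.path("pirna_clusters.tsv"), sep="\t", index=False)
        merged = pirna.merge_clusters_across_tissues(all_clusters)
        self.path("pirna_merged.bed").write_text(to_bed(merged))

    def _stage_report(self) -> None:
        loci = self.final_loci()
        context_df = pd.read_csv(self.path("context.tsv"), sep="\t")
        mirtrons = pd.read_csv(self.path("mirtrons.tsv"), sep="\t")
        clusters = pd.read_csv(self.path("pirna_clusters.tsv"), sep="\t")

        conserved = loci[loci["class"] == "conserved"]
        novel = loci[loci["class"] == "novel"]
        high = conserved[conserved.confidence == "HIGH"]
        low = conserved[conserved.confidence == "LOW"]
        if len(high) + len(low) != len(conserved):
            raise ConsistencyError("conserved != high + low")
        if len(conserved) + len(novel) != len(loci):
            raise ConsistencyError("total != conserved + novel")
        category_counts = context_df.category.value_counts().to_dict()
        if sum(category_counts.values()) != len(loci):
            raise ConsistencyError("context category counts do not sum to total loci")
        if set(context_df.hairpin_id) != set(loci.hairpin_id):
            raise ConsistencyError("context table does not cover the final loci")

        summary = {
            "total_loci": len(loci),
            "conserved": len(conserved),
            "newly_annotated_conserved": int(conserved.newly_annotated.sum()),
            "novel": len(novel),
            "high_confidence_conserved": len(high),
            "low_confidence_conserved": len(low),
            "mirtrons": len(mirtrons),
            "pirna_clusters_total": len(clusters),
        }
        for cat in ("UTR", "EXON", "INTRON", "INTERGENIC"):
            summary[f"context_{cat}"] = int(category_counts.get(cat, 0))
        for tissue in self.tissues():
            summary[f"pirna_clusters_{tissue}"] = int((clusters.tissue == tissue).sum())
        pd.DataFrame(
            [{"metric": k, "value": v} for k, v in summary.items()]
        ).to_csv(self.path("summary.tsv"), sep="\t", index=False)

        ctx_by_id = dict(zip(context_df.hairpin_id, context_df.category))
        mirtron_ids = set(mirtrons.hairpin_id)
        records = []
        for row in loci.to_dict("records"):
            iv = GenomicInterval(row["chrom"], int(row["start"]), int(row["end"]), row["strand"])
            records.append(
                (
                    iv,
                    "miRNA_primary_transcript",
                    {
                        "ID": row["hairpin_id"],
                        "class": row["class"],
                        "confidence": row["confidence"],
                        "context": ctx_by_id.get(row["hairpin_id"], "NA"),
                        "mirtron": "true" if row["hairpin_id"] in mirtron_ids else "false",
                    },
                )
            )
        self.path("annotation.gff3").write_text(to_gff3(records))
        manifest = {
            stage: {name: self.path(name).exists() for name in outputs}
            for stage, outputs in STAGE_OUTPUTS.items()
        }
        self.path("manifest.json").write_text(json.dumps(manifest, indent=1))

    # ------------------------------------------------------------ results
    def summary(self) -> dict[str, int]:
        self._require("report")
        df = pd.read_csv(self.path("summary.tsv"), sep="\t")
        return dict(zip(df.metric, df.value.astype(int)))


def run_all(config: PipelineConfig, force: bool = False) -> Pipeline:
    """Run every stage; returns the pipeline handle for result access."""
    return Pipeline(config).run_all(force=force)
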