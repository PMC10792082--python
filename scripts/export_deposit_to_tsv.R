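#!/usr/bin/env Rscript
# Convert deposited R objects (phyloseq taxonomic profiles + species-specific
# marker-gene tables derived from curatedMetagenomicData) into the four
# interchange TSVs the Python pipeline reads.  The deposit layout is not
# formally documented, so this script introspects what it finds under
# --input-dir and reports every object it could or could not map.
#
# Usage:
#   Rscript scripts/export_deposit_to_tsv.R --input-dir deposit/ --output-dir tsv/
#
# Standalone convenience tooling: the Python package builds and tests fully
# without it.

suppressPackageStartupMessages({
  library(optparse)
})

opts <- parse_args(OptionParser(option_list = list(
  make_option("--input-dir", type = "character", dest = "input_dir"),
  make_option("--output-dir", type = "character", dest = "output_dir")
)))
if (is.null(opts$input_dir) || is.null(opts$output_dir)) {
  stop("both --input-dir and --output-dir are required")
}
dir.create(opts$output_dir, recursive = TRUE, showWarnings = FALSE)

SITE_MAP <- c(
  stool = "stool", feces = "stool",
  saliva = "saliva",
  buccal_mucosa = "buccal_mucosa", buccalmucosa = "buccal_mucosa",
  supragingival_plaque = "supragingival_plaque",
  tongue_dorsum = "tongue_dorsum", tonguedorsum = "tongue_dorsum"
)

normalize_site <- function(x) {
  key <- gsub("[ .-]", "_", tolower(trimws(x)))
  mapped <- SITE_MAP[key]
  if (any(is.na(mapped))) {
    stop("unmappable body-site label(s): ",
         paste(unique(x[is.na(mapped)]), collapse = ", "))
  }
  unname(mapped)
}

write_tsv <- function(df, name) {
  path <- file.path(opts$output_dir, name)
  write.table(df, path, sep = "\t", quote = FALSE, row.names = FALSE)
  cat(sprintf("%s\t%s\t%s\n", name, path, tools::md5sum(path)))
  path
}

rds_files <- list.files(opts$input_dir, pattern = "\\.rds$", ignore.case = TRUE,
                        full.names = TRUE)
if (length(rds_files) == 0) stop("no .rds objects under ", opts$input_dir)

abundance <- NULL; metadata <- NULL; markers <- NULL; marker_map <- NULL

for (path in rds_files) {
  obj <- tryCatch(readRDS(path), error = function(e) {
    stop("unreadable object: ", path, " (", conditionMessage(e), ")")
  })
  cat("found", class(obj)[1], "in", basename(path), "\n")
  if (inherits(obj, "phyloseq")) {
    otu <- as(phyloseq::otu_table(obj), "matrix")
    if (!phyloseq::taxa_are_rows(obj)) otu <- t(otu)
    sd <- data.frame(phyloseq::sample_data(obj))
    site_col <- intersect(c("body_site", "body_subsite", "bodysite"), names(sd))[1]
    subj_col <- intersect(c("subject_id", "subjectID", "subjid"), names(sd))[1]
    if (is.na(site_col) || is.na(subj_col)) {
      stop(basename(path), ": cannot locate body-site/subject columns; found: ",
           paste(names(sd), collapse = ", "))
    }
    metadata <- data.frame(
      sample_id = rownames(sd),
      subject_id = sd[[subj_col]],
      body_site = normalize_site(sd[[site_col]]),
      study_id = if ("study_name" %in% names(sd)) sd$study_name else "deposit",
      visit = if ("visit_number" %in% names(sd)) sd$visit_number else 1L
    )
    nz <- which(otu > 0, arr.ind = TRUE)
    abundance <- data.frame(
      sample_id = colnames(otu)[nz[, "col"]],
      species = rownames(otu)[nz[, "row"]],
      relative_abundance = otu[nz]
    )
  } else if (is.matrix(obj) || is.data.frame(obj)) {
    # marker tables: rows = marker ids (prefixed by species), cols = samples
    m <- as.matrix(obj)
    nz <- which(m > 0, arr.ind = TRUE)
    part <- data.frame(
      sample_id = colnames(m)[nz[, "col"]],
      marker_id = rownames(m)[nz[, "row"]],
      value = m[nz]
    )
    markers <- rbind(markers, part)
    species_guess <- sub("__.*$", "", rownames(m))
    marker_map <- rbind(marker_map,
                        data.frame(marker_id = rownames(m), species = species_guess))
  } else {
    cat("  (skipped: no exporter for this class)\n")
  }
}

if (is.null(abundance)) stop("no phyloseq object found; abundance TSVs not written")
write_tsv(metadata, "metadata.tsv")
write_tsv(abundance, "abundance.tsv")
if (!is.null(markers)) {
  write_tsv(markers, "markers.tsv")
  write_tsv(unique(marker_map), "marker_map.tsv")
} else {
  cat("no marker matrices found; markers.tsv/marker_map.tsv not written\n")
}
cat(sprintf("exported %d abundance rows (nonzero entries preserved)\n",
            nrow(abundance)))
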