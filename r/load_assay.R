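#!/usr/bin/env Rscript
# Load a clonoscope TCR assay CSV (features x cells) into a Seurat assay
# object and print its dimensions. Exits non-zero on any load failure.
#
# Usage: Rscript load_assay.R <assay.csv>

args <- commandArgs(trailingOnly = TRUE)
if (length(args) != 1) stop("usage: Rscript load_assay.R <assay.csv>")
csv <- args[[1]]

suppressMessages({
  library(Matrix)
  library(Seurat)
})

tbl <- read.csv(csv, row.names = 1, check.names = FALSE)
if (nrow(tbl) == 0 || ncol(tbl) == 0) stop("empty assay table")

if (any(grepl("_", rownames(tbl), fixed = TRUE))) {
  message("WARNING: underscore in feature names; Seurat will rewrite them")
}

mat <- as(as.matrix(tbl), "dgCMatrix")
assay <- CreateAssayObject(counts = mat)
cat("ASSAY_DIMS", dim(assay)[1], dim(assay)[2], "\n")
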