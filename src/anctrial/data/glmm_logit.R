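# Batched random-intercept logistic regression via lme4::glmer.
#
# Usage: Rscript glmm_logit.R <data.csv> <out.csv> <fixed_rhs> <re_groups> <ci>
#   data.csv   long table; optional .rep column batches independent fits
#   fixed_rhs  e.g. "arm + stratum + prop_primiparous"
#   re_groups  comma-separated grouping columns, e.g. "cluster_id,pregnancy_id"
#   ci         "none" or "profile" (profile CI for the first RE std.dev.)
#
# Output: one row per fitted quantity:
#   rep,kind,term,estimate,se,lo,hi
#   kind in {coef, vc, meta}; vc rows report the random-intercept std.dev.;
#   meta rows report convergence (1/0) and whether the pregnancy-level random
#   effect was dropped as a fallback after a failed fit.

suppressMessages(library(lme4))

args <- commandArgs(trailingOnly = TRUE)
dat_path <- args[1]; out_path <- args[2]
fixed_rhs <- args[3]; re_groups <- strsplit(args[4], ",")[[1]]
ci_mode <- ifelse(length(args) >= 5, args[5], "none")

dat <- read.csv(dat_path, stringsAsFactors = TRUE)
if (!".rep" %in% names(dat)) dat$.rep <- 0L
for (g in re_groups) dat[[g]] <- factor(dat[[g]])

re_terms <- paste(sprintf("(1|%s)", re_groups), collapse = " + ")
form_full <- as.formula(paste("y ~", fixed_rhs, "+", re_terms))
form_fallback <- as.formula(paste("y ~", fixed_rhs, sprintf("+ (1|%s)", re_groups[1])))

fit_one <- function(d) {
  fallback <- 0L
  fit <- tryCatch(
    suppressWarnings(glmer(form_full, data = d, family = binomial,
                           control = glmerControl(calc.derivs = FALSE))),
    error = function(e) NULL)
  singular_or_failed <- is.null(fit)
  if (!is.null(fit)) {
    conv <- length(fit@optinfo$conv$lme4$messages) == 0
  } else conv <- FALSE
  if (is.null(fit) && length(re_groups) > 1) {
    fallback <- 1L
    fit <- tryCatch(
      suppressWarnings(glmer(form_fallback, data = d, family = binomial,
                             control = glmerControl(calc.derivs = FALSE))),
      error = function(e) NULL)
    conv <- !is.null(fit)
  }
  if (is.null(fit)) {
    return(data.frame(kind = "meta", term = "converged", estimate = 0,
                      se = NA, lo = NA, hi = NA, fallback = fallback))
  }
  co <- summary(fit)$coefficients
  rows <- data.frame(kind = "coef", term = rownames(co),
                     estimate = co[, 1], se = co[, 2], lo = NA, hi = NA,
                     fallback = fallback)
  vc <- as.data.frame(VarCorr(fit))
  vrows <- data.frame(kind = "vc", term = vc$grp, estimate = vc$sdcor,
                      se = NA, lo = NA, hi = NA, fallback = fallback)
  if (ci_mode == "profile") {
    pci <- tryCatch(
      suppressWarnings(suppressMessages(
        confint(fit, parm = "theta_", method = "profile", quiet = TRUE))),
      error = function(e) NULL)
    if (!is.null(pci)) {
      vrows$lo[1] <- pci[1, 1]
      vrows$hi[1] <- pci[1, 2]
    }
  }
  mrow <- data.frame(kind = "meta", term = "converged",
                     estimate = as.numeric(conv), se = NA, lo = NA, hi = NA,
                     fallback = fallback)
  rbind(rows, vrows, mrow)
}

out <- do.call(rbind, lapply(split(dat, dat$.rep), function(d) {
  res <- fit_one(d)
  res$rep <- d$.rep[1]
  res
}))
write.csv(out, out_path, row.names = FALSE)
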