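# Fit one (generalized) linear mixed-effects model and emit a JSON summary.
# Usage: Rscript lme4_runner.R job.json
# job.json: {data: csv path, out: json path, formula, family, reml,
#            optimizer, maxfun, factors: {col: [levels...]}}

suppressMessages({
  library(lme4)
  library(jsonlite)
})

job <- fromJSON(commandArgs(trailingOnly = TRUE)[1])
d <- read.csv(job$data, stringsAsFactors = FALSE)
for (col in names(job$factors)) {
  d[[col]] <- factor(d[[col]], levels = job$factors[[col]])
}

msgs <- character(0)
collect <- function(expr) {
  withCallingHandlers(
    expr,
    warning = function(w) {
      msgs <<- c(msgs, conditionMessage(w))
      invokeRestart("muffleWarning")
    },
    message = function(m) {
      msgs <<- c(msgs, conditionMessage(m))
      invokeRestart("muffleMessage")
    }
  )
}

form <- as.formula(job$formula)
opt <- list(optimizer = job$optimizer, optCtrl = list(maxfun = job$maxfun))
has_random <- length(findbars(form)) > 0

fit <- collect({
  if (job$family == "gaussian") {
    if (has_random) {
      lmer(form, data = d, REML = job$reml,
           control = do.call(lmerControl, opt))
    } else {
      lm(form, data = d)
    }
  } else {
    if (has_random) {
      glmer(form, data = d, family = binomial(),
            control = do.call(glmerControl, opt))
    } else {
      glm(form, data = d, family = binomial())
    }
  }
})

if (has_random) {
  co <- summary(fit)$coefficients
  vc <- as.data.frame(VarCorr(fit))
  conv_msgs <- unlist(fit@optinfo$conv$lme4$messages)
  converged <- fit@optinfo$conv$opt == 0 &&
    !any(grepl("failed to converge", c(msgs, conv_msgs), ignore.case = TRUE))
  singular <- isSingular(fit, tol = 1e-4)
  ll <- logLik(fit)
} else {
  co <- summary(fit)$coefficients
  vc <- data.frame(grp = character(0), var1 = character(0),
                   var2 = character(0), vcov = numeric(0),
                   sdcor = numeric(0))
  converged <- TRUE
  singular <- FALSE
  ll <- logLik(fit)
}

res <- list(
  terms = rownames(co),
  estimate = unname(co[, 1]),
  se = unname(co[, 2]),
  statistic = unname(co[, 3]),
  vcov = as.matrix(vcov(fit)),
  varcorr = list(
    grp = as.character(vc$grp),
    var1 = ifelse(is.na(vc$var1), "", as.character(vc$var1)),
    var2 = ifelse(is.na(vc$var2), "", as.character(vc$var2)),
    vcov = vc$vcov, sdcor = vc$sdcor
  ),
  loglik = as.numeric(ll),
  n_params = attr(ll, "df"),
  bic = BIC(fit),
  n_obs = nobs(fit),
  converged = converged,
  singular = singular,
  is_reml = if (has_random && job$family == "gaussian") isREML(fit) else FALSE,
  messages = msgs
)
write_json(res, job$out, digits = NA, auto_unbox = TRUE, na = "null")
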