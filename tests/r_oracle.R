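# Independent reference route: the same tables analysed with R's own
# mantelhaen.test / glm / lm, plus a direct transcription of the classical
# Woolf (1955) homogeneity statistic.  Input/output via JSON.
suppressMessages(library(jsonlite))

args <- commandArgs(trailingOnly = TRUE)
dat <- fromJSON(args[1], simplifyVector = FALSE)

woolf <- function(x) {
  # x: 2 x 2 x k array with cells (line, allele, replicate)
  a <- x[1, 1, ]; b <- x[1, 2, ]; c <- x[2, 1, ]; d <- x[2, 2, ]
  lor <- log(a * d / (b * c))
  w <- 1 / (1 / a + 1 / b + 1 / c + 1 / d)
  lbar <- sum(w * lor) / sum(w)
  stat <- sum(w * (lor - lbar)^2)
  list(stat = stat, p = pchisq(stat, length(a) - 1, lower.tail = FALSE))
}

out <- list()
for (i in seq_along(dat$tables)) {
  tb <- dat$tables[[i]]
  A <- unlist(tb$counts_a)       # row-major over (replicate, line)
  cov <- unlist(tb$coverage)
  k <- length(A) / 2
  a_cnt <- cov - A
  treat <- factor(rep(c(1, 2), k))
  repl <- factor(rep(seq_len(k), each = 2))

  x <- array(0, dim = c(2, 2, k))
  for (r in seq_len(k)) {
    x[1, 1, r] <- A[2 * r - 1]; x[1, 2, r] <- a_cnt[2 * r - 1]
    x[2, 1, r] <- A[2 * r];     x[2, 2, r] <- a_cnt[2 * r]
  }
  mh <- mantelhaen.test(x, correct = TRUE)
  wf <- woolf(x)

  m1 <- glm(cbind(A, a_cnt) ~ treat * repl, family = binomial, control = glm.control(epsilon = 1e-12))
  av <- anova(m1)
  m2 <- glm(cbind(A, a_cnt) ~ treat, family = binomial, control = glm.control(epsilon = 1e-12))
  s2 <- summary(m2)$coefficients
  qb <- glm(cbind(A, a_cnt) ~ treat, family = quasibinomial, control = glm.control(epsilon = 1e-12))
  sq <- summary(qb)
  lmf <- summary(lm(I(A / cov) ~ treat))$coefficients

  out[[i]] <- list(
    cmh_stat = unname(mh$statistic),
    cmh_p = mh$p.value,
    cmh_or = unname(mh$estimate),
    woolf_stat = wf$stat,
    woolf_p = wf$p,
    m1_dev_treat = av["treat", "Deviance"],
    m1_dev_repl = av["repl", "Deviance"],
    m1_dev_inter = av["treat:repl", "Deviance"],
    m1_p_treat = pchisq(av["treat", "Deviance"], av["treat", "Df"], lower.tail = FALSE),
    m1_p_inter = pchisq(av["treat:repl", "Deviance"], av["treat:repl", "Df"],
                        lower.tail = FALSE),
    m2_coef = unname(s2["treat2", "Estimate"]),
    m2_se = unname(s2["treat2", "Std. Error"]),
    m2_p = unname(s2["treat2", "Pr(>|z|)"]),
    q_coef = unname(sq$coefficients["treat2", "Estimate"]),
    q_se = unname(sq$coefficients["treat2", "Std. Error"]),
    q_p = unname(sq$coefficients["treat2", "Pr(>|t|)"]),
    q_phi = sq$dispersion,
    lm_coef = unname(lmf["treat2", "Estimate"]),
    lm_se = unname(lmf["treat2", "Std. Error"]),
    lm_p = unname(lmf["treat2", "Pr(>|t|)"])
  )
}
write_json(out, args[2], digits = NA, auto_unbox = TRUE)
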