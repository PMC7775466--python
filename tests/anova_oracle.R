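# Independent mixed-ANOVA oracle: type III split-plot via car::Anova on the
# multivariate linear model with sum-to-zero group contrasts.
suppressMessages(library(car))
args <- commandArgs(trailingOnly = TRUE)
d <- read.csv(args[1])
mat <- as.matrix(d[, c("p_stay_rc", "p_stay_rr", "p_stay_uc", "p_stay_ur")])
group <- factor(d$group)
contrasts(group) <- contr.sum(nlevels(group))
mlm <- lm(mat ~ group)
idata <- data.frame(
  reward = factor(c("R", "R", "U", "U")),
  transition = factor(c("C", "R", "C", "R"))
)
a <- Anova(mlm, idata = idata, idesign = ~ reward * transition, type = 3)
s <- summary(a, multivariate = FALSE)$univariate.tests
df <- data.frame(
  effect = rownames(s),
  df1 = s[, "num Df"], df2 = s[, "den Df"],
  F = s[, "F value"], p = s[, "Pr(>F)"]
)
write.csv(df, stdout(), row.names = FALSE)
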