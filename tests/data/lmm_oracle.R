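# Independent mixed-model oracle: fits the fixture dataset with
# lme4/lmerTest/emmeans and writes the reference quantities compared by
# tests/test_lmm.py. Run from the repository root:
#   Rscript tests/data/lmm_oracle.R
suppressMessages({library(lme4); library(lmerTest); library(emmeans); library(jsonlite)})
d <- read.csv("tests/data/lmm_fixture.csv")
d$group <- factor(d$group, levels=c("young","old"))
d$condition <- factor(d$condition, levels=c("level","ascent","descent"))
contrasts(d$group) <- contr.sum(2)
contrasts(d$condition) <- contr.sum(3)
d$velocity_c <- d$velocity - mean(d$velocity)
m <- lmer(value ~ velocity_c + group*condition + (1|participant), data=d, REML=TRUE)
an <- anova(m, type=3)   # lmerTest: Satterthwaite
vc <- as.data.frame(VarCorr(m))
emm <- emmeans(m, ~ group | condition, lmer.df="satterthwaite")
ct <- as.data.frame(pairs(emm))   # young - old per condition
out <- list(
  sigma2_participant = vc$vcov[1],
  sigma2_resid = vc$vcov[2],
  fixef = as.list(fixef(m)),
  anova = lapply(rownames(an), function(r) list(term=r, F=an[r,"F value"],
           df_num=an[r,"NumDF"], df_den=an[r,"DenDF"], p=an[r,"Pr(>F)"])),
  contrasts = lapply(seq_len(nrow(ct)), function(i) list(
      condition=as.character(ct$condition[i]), estimate=ct$estimate[i],
      se=ct$SE[i], df=ct$df[i], p=ct$p.value[i]))
)
writeLines(toJSON(out, auto_unbox=TRUE, digits=12), "tests/data/lmm_expected.json")
cat("oracle written\n")
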