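issue_id,source,n_countries,arg_adv,change_prereg,change_prereg_ci_low,change_prereg_ci_high,change_alter,change_alter_ci_low,change_alter_ci_high
homosexuality,WVS/EVS,92,0.57,0.66,0.59,0.72,0.64,0.64,0.65
divorce,WVS/EVS,93,0.44,0.39,0.34,0.45,0.36,0.35,0.37
woman single parent,WVS/EVS,70,0.43,0.23,0.17,0.30,0.21,0.20,0.22
sex before marriage,WVS/EVS,31,0.35,,,,0.22,0.17,0.27
prostitution,WVS/EVS,87,0.33,0.23,0.17,0.29,0.25,0.24,0.26
enjoying sexual freedom,WVS/EVS,42,0.33,,,,0.25,0.22,0.28
taking soft drugs,WVS/EVS,45,0.23,,,,0.53,0.51,0.55
abortion,WVS/EVS,93,0.20,0.28,0.22,0.34,0.24,0.23,0.25
euthanasia,WVS/EVS,91,0.19,0.30,0.25,0.36,0.23,0.23,0.24
suicide,WVS/EVS,93,0.18,0.22,0.16,0.29,0.23,0.22,0.24
adultery,WVS/EVS,37,0.07,,,,-0.25,-0.28,-0.23
lying,WVS/EVS,38,0.01,,,,-0.07,-0.10,-0.05
keeping money that one found,WVS/EVS,16,0.00,,,,0.34,0.27,0.41
parents' duty even at own expense,WVS/EVS,60,-0.08,0.18,0.11,0.24,0.16,0.15,0.17
killing in self-defence,WVS/EVS,16,-0.14,,,,0.00,-0.05,0.05
respect & love for parents,WVS/EVS,60,-0.15,-0.08,-0.14,-0.02,-0.07,-0.08,-0.06
parents beating children,WVS/EVS,35,-0.28,,,,0.14,0.08,0.21
following instructions at work,WVS/EVS,60,-0.32,-0.03,-0.09,0.03,0.00,-0.01,0.01
immigrant having same rights,ISSP,25,0.47,-0.16,-0.37,0.05,-0.24,-0.27,-0.21
cohabiting unmarried,ISSP,34,0.45,0.18,0.08,0.29,0.14,0.13,0.16
organizing protest marches,ISSP,31,0.39,0.17,0.09,0.25,0.14,0.12,0.16
organizing protest meetings,ISSP,31,0.38,0.08,0.02,0.14,0.07,0.05,0.09
convicting innocent worse,ISSP,31,0.31,-0.02,-0.10,0.06,-0.06,-0.08,-0.05
helping friends who are less well off,ISSP,20,0.08,-0.02,-0.09,0.06,-0.07,-0.09,-0.05
holding meetings against an ethnic group,ISSP,29,-0.06,0.08,-0.10,0.27,0.17,0.13,0.21
extramarital sex wrong,ISSP,37,-0.13,0.05,-0.09,0.19,0.01,0.03,0.08
abortion because of defect wrong,ISSP,30,-0.14,0.01,-0.08,0.09,0.06,-0.00,0.03
taking care of self before helping others,ISSP,20,-0.15,0.07,-0.01,0.15,0.08,0.05,0.10
abortion because of low income wrong,ISSP,36,-0.19,-0.04,-0.15,0.07,-0.04,-0.05,-0.03
marry to have children,ISSP,35,-0.31,-0.37,-0.48,-0.26,-0.37,-0.40,-0.37
premarital sex wrong,ISSP,30,-0.35,-0.13,-0.25,-0.02,-0.20,-0.22,-0.17
follow traditional gender roles,ISSP,42,-0.45,-0.34,-0.41,-0.27,-0.38,-0.40,-0.37
homosexual relations wrong,ISSP,37,-0.53,-0.49,-0.58,-0.41,-0.50,-0.51,-0.49
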