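{"sigma2_participant":12.066764643366,"sigma2_resid":3.615682633588,"fixef":{"(Intercept)":25.821875319445,"velocity_c":3.317474830473,"group1":-2.797924192467,"condition1":-3.466119864756,"condition2":4.132378898909,"group1:condition1":0.7414668314788,"group1:condition2":-1.071848850464},"anova":[{"term":"velocity_c","F":2.112330277021,"df_num":1,"df_den":47.003105455956,"p":0.1527611283232},{"term":"group","F":13.838427714955,"df_num":1,"df_den":22.867709529352,"p":0.001132871822068},{"term":"condition","F":97.462088666665,"df_num":2,"df_den":43.03007145058,"p":1.047906707134e-16},{"term":"group:condition","F":5.88883400683,"df_num":2,"df_den":43.065109749257,"p":0.005485464465411}],"contrasts":[{"condition":"level","estimate":-4.112914721977,"se":1.619954520537,"df":30.293027205596,"p":0.01648742519859},{"condition":"ascent","estimate":-7.739546085863,"se":1.642951442488,"df":31.747720902476,"p":4.673691937475e-05},{"condition":"descent","estimate":-4.935084346965,"se":1.640967083052,"df":31.621842199691,"p":0.005131498930563}]}
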