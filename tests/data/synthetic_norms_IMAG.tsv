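# dimension=IMAG
# synthetic fixture ratings for testing; NOT the published norms
answer	3.03	1	7
apple	6.8	1	7
ball	6.684	1	7
belief	1.435	1	7
bird	6.6115	1	7
book	6.655	1	7
bread	6.655	1	7
car	6.6985	1	7
cat	6.655	1	7
chair	6.771	1	7
chance	2.16	1	7
city	5.64	1	7
concept	1.725	1	7
cup	6.655	1	7
dog	6.5825	1	7
egg	6.65	1	7
essence	1.3625	1	7
faith	1.406	1	7
family	4.77	1	7
fish	6.597	1	7
flower	6.568	1	7
freedom	1.725	1	7
friend	5.205	1	7
game	4.915	1	7
garden	6.22	1	7
honor	1.7975	1	7
hope	1.261	1	7
house	6.7275	1	7
idea	1.87	1	7
journey	3.61	1	7
justice	1.6525	1	7
letter	6.075	1	7
logic	1.87	1	7
luck	2.0875	1	7
market	5.785	1	7
meaning	1.551	1	7
moment	2.305	1	7
morning	3.755	1	7
mountain	6.51	1	7
music	4.045	1	7
principle	1.29	1	7
problem	2.45	1	7
question	2.74	1	7
reason	2.305	1	7
responsibility	1.5075	1	7
river	6.51	1	7
school	5.93	1	7
shoe	6.626	1	7
spirit	2.305	1	7
stone	6.5535	1	7
story	3.32	1	7
table	6.655	1	7
theory	2.015	1	7
tree	6.742	1	7
truth	1.58	1	7
virtue	1.609	1	7
water	6.6405	1	7
window	6.365	1	7
wisdom	1.9425	1	7
work	4.19	1	7
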