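# dimension=CONC
# synthetic fixture ratings for testing; NOT the published norms
answer	2.4	1	5
apple	5	1	5
ball	4.92	1	5
belief	1.3	1	5
bird	4.87	1	5
book	4.9	1	5
bread	4.9	1	5
car	4.93	1	5
cat	4.9	1	5
chair	4.98	1	5
chance	1.8	1	5
city	4.2	1	5
concept	1.5	1	5
cup	4.9	1	5
dog	4.85	1	5
egg	4.97	1	5
essence	1.25	1	5
faith	1.28	1	5
family	3.6	1	5
fish	4.86	1	5
flower	4.84	1	5
freedom	1.5	1	5
friend	3.9	1	5
game	3.7	1	5
garden	4.6	1	5
honor	1.55	1	5
hope	1.18	1	5
house	4.95	1	5
idea	1.6	1	5
journey	2.8	1	5
justice	1.45	1	5
letter	4.5	1	5
logic	1.6	1	5
luck	1.75	1	5
market	4.3	1	5
meaning	1.38	1	5
moment	1.9	1	5
morning	2.9	1	5
mountain	4.8	1	5
music	3.1	1	5
principle	1.2	1	5
problem	2	1	5
question	2.2	1	5
reason	1.9	1	5
responsibility	1.35	1	5
river	4.8	1	5
school	4.4	1	5
shoe	4.88	1	5
spirit	1.9	1	5
stone	4.83	1	5
story	2.6	1	5
table	4.9	1	5
theory	1.7	1	5
tree	4.96	1	5
truth	1.4	1	5
virtue	1.42	1	5
water	4.89	1	5
window	4.7	1	5
wisdom	1.65	1	5
work	3.2	1	5
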