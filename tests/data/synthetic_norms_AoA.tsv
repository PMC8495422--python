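# dimension=AoA
# synthetic fixture ratings for testing; NOT the published norms
answer	3.3	1	7
apple	1.9	1	7
ball	1.8	1	7
belief	5.2	1	7
bird	2.2	1	7
book	2.3	1	7
bread	2.4	1	7
car	2	1	7
cat	1.75	1	7
chair	2.5	1	7
chance	4.3	1	7
city	3.4	1	7
concept	5.9	1	7
cup	2	1	7
dog	1.7	1	7
egg	1.89	1	7
essence	6.2	1	7
faith	5	1	7
family	2.6	1	7
fish	2.2	1	7
flower	2.4	1	7
freedom	5	1	7
friend	2.6	1	7
game	2.5	1	7
garden	3	1	7
honor	5.4	1	7
hope	4.4	1	7
house	2	1	7
idea	4.2	1	7
journey	4.6	1	7
justice	5.6	1	7
letter	3.1	1	7
logic	5.9	1	7
luck	4	1	7
market	3.6	1	7
meaning	4.7	1	7
moment	4.2	1	7
morning	2.7	1	7
mountain	3.2	1	7
music	3	1	7
principle	6	1	7
problem	4	1	7
question	3.3	1	7
reason	4.4	1	7
responsibility	5.6	1	7
river	3.2	1	7
school	2.8	1	7
shoe	2.1	1	7
spirit	4.8	1	7
stone	3	1	7
story	2.9	1	7
table	2.5	1	7
theory	5.8	1	7
tree	2.1	1	7
truth	4.5	1	7
virtue	6.1	1	7
water	1.6	1	7
window	2.8	1	7
wisdom	5.5	1	7
work	3.2	1	7
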